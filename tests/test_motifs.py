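"""Motif scanning and grammar statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisgrammar import (
    MotifModel,
    PeakSequence,
    cooccurrence_enrichment,
    differential_cooccurrence,
    differential_motif_enrichment,
    dinucleotide_shuffle,
    enrichment_vs_background,
    load_motifs,
    motif_density_profile,
    motif_presence,
    mutate_motif_sites,
    reverse_complement,
    scan_motif_set,
    scan_motifs,
    spacing_profile,
)
from cisgrammar.motifs import IUPAC


def _brute_force_hits(seq, consensus):
    """Exhaustive two-strand IUPAC enumeration (independent of the scanner)."""
    def matches(s, pat):
        return len(s) == len(pat) and all(a in IUPAC[b] for a, b in zip(s, pat))

    k = len(consensus)
    rc = reverse_complement(consensus)
    palindromic = consensus == rc
    hits = []
    for i in range(len(seq) - k + 1):
        win = seq[i : i + k]
        if matches(win, consensus):
            hits.append((i, "+"))
        if not palindromic and matches(win, rc):
            hits.append((i, "-"))
    return hits


class TestScan:
    def test_simple_forward_hit(self):
        occ = scan_motifs(
            [PeakSequence("p", "GGTAATCCGG", 0)],
            MotifModel("K50", "TAATCC", "K50"),
        )
        assert len(occ) == 1
        assert tuple(occ.iloc[0][["offset", "strand"]]) == (2, "+")

    def test_reverse_hit(self):
        # GGATTA is the reverse complement of TAATCC
        occ = scan_motifs(
            [PeakSequence("p", "AGGATTAG", 0)],
            MotifModel("K50", "TAATCC", "K50"),
        )
        assert len(occ) == 1
        assert tuple(occ.iloc[0][["offset", "strand"]]) == (1, "-")

    def test_palindrome_collapses_to_single_plus_hit(self):
        occ = scan_motifs(
            [PeakSequence("p", "GCACGTGC", 0)],
            MotifModel("Ebox_core", "CACGTG", "Ebox"),
        )
        assert len(occ) == 1
        assert occ.iloc[0]["strand"] == "+"

    def test_offsets_are_summit_relative(self):
        occ = scan_motifs(
            [PeakSequence("p", "GGTAATCCGG", 5)],
            MotifModel("K50", "TAATCC", "K50"),
        )
        assert occ.iloc[0]["offset"] == -3

    @pytest.mark.parametrize("consensus", ["TAATCC", "TAATTR", "CANNTG", "RGGTCA"])
    def test_matches_bruteforce_enumeration(self, consensus):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        occ = scan_motifs(
            [PeakSequence("p", seq, 0)], MotifModel("m", consensus, "other")
        )
        got = sorted(zip(occ["offset"], occ["strand"]))
        assert got == sorted(_brute_force_hits(seq, consensus))

    def test_reverse_complement_consistency(self):
        """Scanning the reverse complement swaps strands and reflects offsets."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        motif = MotifModel("m", "TAATCC", "K50")
        fwd = scan_motifs([PeakSequence("p", seq, 0)], motif)
        rev = scan_motifs([PeakSequence("p", reverse_complement(seq), 0)], motif)
        k = len(motif.consensus)
        mapped = sorted(
            (len(seq) - k - off, "+" if strand == "-" else "-")
            for off, strand in zip(rev["offset"], rev["strand"])
        )
        assert mapped == sorted(zip(fwd["offset"], fwd["strand"]))

    def test_non_iupac_motif_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("bad", "TAATXX", "other")

    def test_shipped_motif_set_loads(self):
        motifs = load_motifs()
        assert {m.family for m in motifs} >= {"K50", "Q50", "Ebox", "CTCF"}


class TestPresence:
    def test_multiplicity_ignored(self):
        occ = pd.DataFrame(
            {
                "peak_id": ["p1", "p1", "p1"],
                "offset": [0, 5, 9],
                "strand": ["+", "+", "-"],
                "score": [1.0] * 3,
                "motif": ["m"] * 3,
            }
        )
        table = motif_presence(["p1", "p2"], occ)
        assert bool(table.loc["p1", "m"]) and not bool(table.loc["p2", "m"])

    def test_column_sums_match_distinct_peak_counts(self, small_dataset):
        genome, peak_sets, _ = small_dataset
        from cisgrammar import peak_sequences

        seqs = peak_sequences(genome, peak_sets["photoreceptor"])[:100]
        occ = scan_motif_set(seqs, load_motifs())
        table = motif_presence([s.peak_id for s in seqs], occ)
        for motif in table.columns:
            distinct = occ.loc[occ["motif"] == motif, "peak_id"].nunique()
            assert table[motif].sum() == distinct


class TestEnrichmentVsBackground:
    def test_absent_motif_p_is_one(self):
        seqs = [PeakSequence("p1", "ACGTACGTACGTACGTACGT", 10)]
        res = enrichment_vs_background(
            seqs, [MotifModel("mads", "CTAAAAATAG", "MADS")], seed=0
        )
        assert res.iloc[0]["p_value"] == 1.0

    def test_planted_motif_ranks_first(self, small_dataset):
        genome, peak_sets, _ = small_dataset
        from cisgrammar import peak_sequences

        seqs = peak_sequences(genome, peak_sets["photoreceptor"])[:150]
        res = enrichment_vs_background(seqs, load_motifs(), seed=1)
        best = res.sort_values("p_value").iloc[0]
        assert best["motif"] == "K50_HD"  # densest planted family
        assert best["fdr"] < 0.05

    def test_shuffle_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400, p=[0.4, 0.1, 0.1, 0.4]))
        shuf = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert dinucs(shuf) == dinucs(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
        assert shuf != seq  # astronomically unlikely to be identical

    def test_empty_peak_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_vs_background([], load_motifs())


class TestDifferentialEnrichment:
    @staticmethod
    def _presence(count, total, name="m"):
        vals = [True] * count + [False] * (total - count)
        return pd.DataFrame({name: vals}, index=[f"p{i}" for i in range(total)])

    def test_equal_proportions_z_zero_p_one(self):
        res = differential_motif_enrichment(
            self._presence(50, 100), self._presence(50, 100)
        )
        assert res.iloc[0]["statistic"] == pytest.approx(0.0)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_matches_pooled_proportion_formula(self):
        """60/100 vs 40/100 against the hand-computed pooled z-test."""
        res = differential_motif_enrichment(
            self._presence(60, 100), self._presence(40, 100)
        )
        p_pool = (60 + 40) / 200
        z = (0.6 - 0.4) / np.sqrt(p_pool * (1 - p_pool) * (1 / 100 + 1 / 100))
        p = 2 * stats.norm.sf(abs(z))
        assert res.iloc[0]["statistic"] == pytest.approx(z)
        assert res.iloc[0]["p_value"] == pytest.approx(p)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            differential_motif_enrichment(
                self._presence(5, 10), self._presence(0, 0)
            )

    def test_type_one_error_near_nominal(self):
        """Null two-proportion test rejects at ~alpha (within 3 SE)."""
        rng = np.random.default_rng(11)
        n_sim, n, p0, alpha = 2000, 400, 0.4, 0.05
        rejections = 0
        for _ in range(n_sim):
            ca, cb = rng.binomial(n, p0), rng.binomial(n, p0)
            pool = (ca + cb) / (2 * n)
            if pool in (0, 1):
                continue
            z = (ca / n - cb / n) / np.sqrt(pool * (1 - pool) * 2 / n)
            if 2 * stats.norm.sf(abs(z)) < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 3 * se

    def test_bh_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(12)
        pres_a = pd.DataFrame(
            rng.random((200, 10)) < rng.random(10),
            columns=[f"m{i}" for i in range(10)],
        )
        pres_b = pd.DataFrame(
            rng.random((200, 10)) < rng.random(10),
            columns=[f"m{i}" for i in range(10)],
        )
        res = differential_motif_enrichment(pres_a, pres_b).sort_values("p_value")
        assert res["fdr"].is_monotonic_increasing


class TestDensityProfile:
    def test_point_mass_at_summit(self):
        occ = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(1000)], "offset": 0,
             "strand": "+", "score": 1.0, "motif": "m"}
        )
        prof = motif_density_profile(occ, n_peaks=1000, window=10, bin_size=1)
        # 1000 occurrences / (1 bp x 1000 peaks / 1000) = 1000 per bp per 1000 peaks
        assert prof.loc[prof["bin_center"] == 0.5, "density"].iloc[0] == 1000.0
        assert prof.loc[prof["bin_center"] != 0.5, "density"].sum() == 0.0

    def test_conservation_of_total_count(self):
        rng = np.random.default_rng(13)
        occ = pd.DataFrame(
            {"peak_id": "p", "offset": rng.integers(-500, 500, size=777),
             "strand": "+", "score": 1.0, "motif": "m"}
        )
        prof = motif_density_profile(occ, n_peaks=250, window=1000, bin_size=20)
        total = (prof["density"] * 20 * 250 / 1000).sum()
        in_window = ((occ["offset"] >= -500) & (occ["offset"] < 500)).sum()
        assert total == pytest.approx(in_window)

    def test_zero_peaks_rejected(self):
        with pytest.raises(ValueError):
            motif_density_profile(pd.DataFrame({"offset": []}), n_peaks=0)


class TestCooccurrence:
    @staticmethod
    def _table(n, n1, n2, obs):
        a = np.zeros(n, dtype=bool)
        b = np.zeros(n, dtype=bool)
        a[:n1] = True
        b[:obs] = True
        b[n1 : n1 + (n2 - obs)] = True
        return pd.DataFrame({"m1": a, "m2": b})

    def test_observed_equal_expected_gives_zero(self):
        # N=100, n1=50, n2=40, obs=20 -> expected 20, enrichment 0
        res = cooccurrence_enrichment(self._table(100, 50, 40, 20))
        assert res.iloc[0]["expected"] == pytest.approx(20.0)
        assert res.iloc[0]["log2_enrichment"] == pytest.approx(0.0)

    def test_twofold_enrichment(self):
        # obs=39, exp=19 -> log2(40/20) = 1
        res = cooccurrence_enrichment(self._table(100, 40, 47, 39))
        assert res.iloc[0]["expected"] == pytest.approx(40 * 47 / 100)
        assert res.iloc[0]["log2_enrichment"] == pytest.approx(
            np.log2(40 / (40 * 47 / 100 + 1))
        )

    def test_formula_against_direct_counting(self):
        rng = np.random.default_rng(14)
        pres = pd.DataFrame(
            rng.random((300, 6)) < 0.4, columns=[f"m{i}" for i in range(6)]
        )
        res = cooccurrence_enrichment(pres)
        for row in res.itertuples(index=False):
            obs = int((pres[row.motif_a] & pres[row.motif_b]).sum())
            exp = pres[row.motif_a].sum() * pres[row.motif_b].sum() / len(pres)
            assert row.observed == obs
            assert row.log2_enrichment == pytest.approx(
                np.log2((obs + 1) / (exp + 1))
            )

    def test_exact_paper_arithmetic(self):
        # obs=39 pairs with exp=19 -> log2((39+1)/(19+1)) = 1.0 exactly
        assert np.log2((39 + 1) / (19 + 1)) == pytest.approx(1.0)


class TestDifferentialCooccurrence:
    def test_identical_proportions_p_one(self):
        pres = pd.DataFrame(
            {"m1": [True] * 10 + [False] * 10, "m2": [True] * 10 + [False] * 10}
        )
        res = differential_cooccurrence(pres, pres.copy())
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_tail_sum(self):
        """Two-sided Fisher p for table (8,2;2,8) by exhaustive enumeration."""
        ca, na, cb, nb = 8, 10, 2, 10
        pres_a = pd.DataFrame(
            {"m1": [True] * ca + [False] * (na - ca), "m2": [True] * na}
        )
        pres_b = pd.DataFrame(
            {"m1": [True] * cb + [False] * (nb - cb), "m2": [True] * nb}
        )
        res = differential_cooccurrence(pres_a, pres_b, pairs=[("m1", "m2")])
        # hypergeometric enumeration: fix margins (10, 10, 10)
        total, k = na + nb, ca + cb
        probs = [stats.hypergeom.pmf(x, total, k, na) for x in range(k + 1)]
        p_obs = stats.hypergeom.pmf(ca, total, k, na)
        expected = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert res.iloc[0]["p_value"] == pytest.approx(expected)

    def test_swapping_sets_leaves_p_unchanged(self):
        rng = np.random.default_rng(15)
        pres_a = pd.DataFrame(rng.random((50, 3)) < 0.5, columns=list("xyz"))
        pres_b = pd.DataFrame(rng.random((70, 3)) < 0.3, columns=list("xyz"))
        res1 = differential_cooccurrence(pres_a, pres_b)
        res2 = differential_cooccurrence(pres_b, pres_a)
        assert np.allclose(res1["p_value"], res2["p_value"])


class TestSpacing:
    @staticmethod
    def _occ(peak, offset, strand, motif):
        return {"peak_id": peak, "offset": offset, "strand": strand,
                "score": 1.0, "motif": motif}

    def test_downstream_same_strand_spike(self):
        anchors = pd.DataFrame([self._occ("p", 0, "+", "a")])
        secondaries = pd.DataFrame([self._occ("p", 10, "+", "b")])
        prof = spacing_profile(anchors, secondaries, window=100, bin_size=1)
        same = prof[prof["strand"] == "same"].set_index("bin_center")
        assert same.loc[10.5, "count"] == 1
        assert same["count"].sum() == 1
        assert prof[prof["strand"] == "opposite"]["count"].sum() == 0

    def test_minus_strand_anchor_orientation_normalized(self):
        anchors = pd.DataFrame([self._occ("p", 0, "-", "a")])
        secondaries = pd.DataFrame([self._occ("p", 10, "-", "b")])
        prof = spacing_profile(anchors, secondaries, window=100, bin_size=1)
        same = prof[prof["strand"] == "same"].set_index("bin_center")
        assert same.loc[-9.5, "count"] == 1  # downstream of a - anchor is -10

    def test_self_pairs_excluded(self):
        anchors = pd.DataFrame([self._occ("p", 0, "+", "a")])
        prof = spacing_profile(anchors, anchors.copy(), window=100, bin_size=1)
        assert prof["count"].sum() == 0

    def test_reflection_negates_offsets(self):
        rng = np.random.default_rng(16)
        anchors = pd.DataFrame(
            [self._occ("p", int(o), "+", "a") for o in rng.integers(-50, 50, 5)]
        )
        secondaries = pd.DataFrame(
            [self._occ("p", int(o), "+", "b") for o in rng.integers(-50, 50, 20)]
        )
        prof = spacing_profile(anchors, secondaries, window=200, bin_size=1)
        refl_anchors = anchors.assign(offset=-anchors["offset"])
        refl_sec = secondaries.assign(offset=-secondaries["offset"])
        prof_r = spacing_profile(refl_anchors, refl_sec, window=200, bin_size=1)
        # with 1 bp bins, bin center d+0.5 holds integer offset d
        def by_offset(p):
            sub = p[p["strand"] == "same"]
            return {
                int(c - 0.5): n
                for c, n in zip(sub["bin_center"], sub["count"]) if n > 0
            }
        orig, refl = by_offset(prof), by_offset(prof_r)
        assert orig == {-d: n for d, n in refl.items()}

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError):
            spacing_profile(pd.DataFrame(), pd.DataFrame())


class TestMutagenesis:
    def test_null_mutation_taat_to_tggt(self):
        assert mutate_motif_sites("TAATCC", [(0, "null")]) == "TGGTCC"

    def test_q50_conversion(self):
        assert mutate_motif_sites("TAATCC", [(0, "q50")]) == "TAATTA"

    def test_surrounding_bases_untouched(self):
        seq = "GGTAATCCGGTAATTAGG"
        out = mutate_motif_sites(seq, [(2, "null"), (10, "q50")])
        assert out == "GGTGGTCCGGTAATTAGG"
        assert len(out) == len(seq)

    def test_empty_site_list_is_identity(self):
        assert mutate_motif_sites("ACGT", []) == "ACGT"

    def test_non_taat_site_rejected(self):
        with pytest.raises(ValueError):
            mutate_motif_sites("TGGTCC", [(0, "null")])
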