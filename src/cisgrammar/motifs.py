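"""Motif scanning and cis-regulatory grammar statistics.

The grammar of a cell class is summarised here as the identity, frequency,
co-occurrence, spacing and orientation of transcription-factor binding-site
motifs within its open chromatin regions.  Motifs are IUPAC consensus
models (a small curated set ships with the package, covering the motif
families central to photoreceptor/bipolar regulation: K50 and Q50
homeodomain sites, E-boxes, CTCF, nuclear-receptor and MADS-box sites).

Statistics provided:

* single-set enrichment against a dinucleotide-shuffled background
  (one-sided binomial test on the proportion of peaks containing a motif);
* differential enrichment between two peak sets (two-sample test of equal
  proportions, i.e. a pooled z-test without continuity correction);
* summit-anchored motif density profiles (motifs per bp per 1000 peaks);
* motif-pair co-occurrence enrichment, log2((observed+1)/(expected+1))
  with expected = n1 * n2 / N under independence;
* differential co-occurrence between peak sets (Fisher's exact test);
* spacing/orientation profiles of a secondary motif around anchor motifs;
* in-silico motif mutagenesis (TAAT core knockout, K50 -> Q50 conversion).

Benjamini-Hochberg correction is applied within each analysis (across
motifs, or across pairs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MOTIF_FAMILIES = ("K50", "Q50", "Ebox", "CTCF", "NR", "MADS", "other")


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """An IUPAC consensus motif with a family tag.

    ``weight_matrix`` (positions x ACGT log-odds) and ``threshold`` enable
    score-based matching; by default matching is exact consensus matching.
    """

    name: str
    consensus: str
    family: str = "other"
    weight_matrix: tuple[tuple[float, float, float, float], ...] | None = None
    threshold: float | None = None

    def __post_init__(self):
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        bad = [c for c in self.consensus if c not in IUPAC]
        if bad:
            raise ValueError(
                f"motif {self.name}: non-IUPAC characters {bad} in consensus"
            )
        if self.family not in MOTIF_FAMILIES:
            raise ValueError(f"motif {self.name}: unknown family {self.family!r}")
        if self.weight_matrix is not None:
            if len(self.weight_matrix) != len(self.consensus):
                raise ValueError(f"motif {self.name}: matrix length mismatch")
            if self.threshold is None or not np.isfinite(self.threshold):
                raise ValueError(
                    f"motif {self.name}: weight matrix requires a finite threshold"
                )

    @property
    def is_palindromic(self) -> bool:
        return self.consensus == reverse_complement(self.consensus)


@dataclass(frozen=True)
class PeakSequence:
    """A peak-anchored sequence with the summit offset within it."""

    peak_id: str
    sequence: str
    summit: int

    def __post_init__(self):
        if not (0 <= self.summit < len(self.sequence)):
            raise ValueError(f"peak {self.peak_id}: summit outside sequence")


def load_motifs(path: str | Path | None = None) -> list[MotifModel]:
    """Load a motif set from a TSV (name, consensus, family).

    Without a path, the curated set shipped with the package is returned.
    """
    if path is None:
        src = resources.files("cisgrammar").joinpath("data/motifs.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        MotifModel(str(r.name), str(r.consensus), str(r.family))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _iupac_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def _pwm_scan(seq: str, motif: MotifModel) -> list[tuple[int, str, float]]:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = np.asarray(motif.weight_matrix)
    k = len(motif.consensus)
    hits = []
    enc = np.array([base_idx.get(b, -1) for b in seq])
    for strand, mat in (("+", w), ("-", w[::-1, ::-1])):
        for i in range(len(seq) - k + 1):
            window = enc[i : i + k]
            if (window < 0).any():
                continue
            score = float(mat[np.arange(k), window].sum())
            if score >= motif.threshold:
                hits.append((i, strand, score))
    return hits


def scan_motifs(
    peak_seqs: Iterable[PeakSequence], motif: MotifModel
) -> pd.DataFrame:
    """Scan peak sequences for a motif on both strands.

    Returns occurrences with summit-relative offsets (offset of the match
    start).  For a palindromic consensus, the forward and reverse hits at a
    given position are the same site and collapse to a single '+'
    occurrence.  Matching is exact IUPAC consensus matching unless the
    motif carries a weight matrix and threshold.
    """
    rows = []
    if motif.weight_matrix is not None:
        for ps in peak_seqs:
            for pos, strand, score in _pwm_scan(ps.sequence.upper(), motif):
                rows.append((ps.peak_id, pos - ps.summit, strand, score, motif.name))
        return _occurrence_frame(rows)

    fwd = _iupac_regex(motif.consensus)
    rev = None if motif.is_palindromic else _iupac_regex(
        reverse_complement(motif.consensus)
    )
    for ps in peak_seqs:
        seq = ps.sequence.upper()
        for m in fwd.finditer(seq):
            rows.append((ps.peak_id, m.start() - ps.summit, "+", 1.0, motif.name))
        if rev is not None:
            for m in rev.finditer(seq):
                rows.append((ps.peak_id, m.start() - ps.summit, "-", 1.0, motif.name))
    return _occurrence_frame(rows)


def _occurrence_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["peak_id", "offset", "strand", "score", "motif"]
    )


def scan_motif_set(
    peak_seqs: Sequence[PeakSequence], motifs: Sequence[MotifModel]
) -> pd.DataFrame:
    """Scan a set of motifs; concatenated occurrence table."""
    frames = [f for f in (scan_motifs(peak_seqs, m) for m in motifs) if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else _occurrence_frame([])


def motif_presence(
    peak_ids: Sequence[str], occurrences: pd.DataFrame
) -> pd.DataFrame:
    """Peak x motif boolean table: presence = at least one occurrence.

    Multiplicity is deliberately ignored: all downstream proportion
    statistics are about the proportion of peaks *containing* a motif.
    """
    motifs = sorted(occurrences["motif"].unique()) if len(occurrences) else []
    table = pd.DataFrame(False, index=list(peak_ids), columns=motifs)
    for motif, sub in occurrences.groupby("motif"):
        present = sub["peak_id"].unique()
        present = [p for p in present if p in table.index]
        table.loc[present, motif] = True
    return table


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (background model)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Implements the Eulerian-path construction: the sequence is a walk on
    the nucleotide graph whose edges are its dinucleotides; a random walk
    with the same edge multiset and endpoints is produced by fixing, for
    every vertex except the final one, a random last-out edge such that the
    last-edge graph is connected to the final vertex, then shuffling the
    remaining out-edges.
    """
    seq = seq.upper()
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    start, end = seq[0], seq[-1]
    vertices = sorted(edges)

    for _ in range(1000):
        last = {}
        for v in vertices:
            if v == end and not edges[v]:
                continue
            if v != end:
                last[v] = edges[v][rng.integers(len(edges[v]))]
        # check every non-end vertex reaches end through last-edges
        ok = True
        for v in last:
            cur, steps = v, 0
            while cur != end and cur in last and steps <= len(vertices):
                cur = last[cur]
                steps += 1
            if cur != end:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - graph is tiny, failure here is unreachable
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")

    ordered: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last:
            pool.remove(last[v])
        rng.shuffle(pool)
        if v in last:
            pool.append(last[v])
        ordered[v] = pool

    out = [start]
    cur = start
    for _ in range(len(seq) - 1):
        nxt = ordered[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def enrichment_vs_background(
    peak_seqs: Sequence[PeakSequence],
    motifs: Sequence[MotifModel],
    n_shuffles: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif enrichment in peaks vs dinucleotide-shuffled background.

    The background is ``n_shuffles`` dinucleotide-preserving shuffles of
    the peak sequences themselves, which preserves composition.  For each
    motif, a one-sided binomial test asks whether the proportion of peaks
    containing the motif exceeds the background proportion; p-values are
    BH-adjusted across motifs.
    """
    if not peak_seqs:
        raise ValueError("enrichment_vs_background requires a non-empty peak set")
    rng = np.random.default_rng(seed)
    background = [
        PeakSequence(f"{ps.peak_id}_shuf{i}", dinucleotide_shuffle(ps.sequence, rng),
                     ps.summit)
        for i in range(n_shuffles)
        for ps in peak_seqs
    ]
    occ_fg = scan_motif_set(peak_seqs, motifs)
    occ_bg = scan_motif_set(background, motifs)
    n_fg, n_bg = len(peak_seqs), len(background)
    pres_fg = motif_presence([p.peak_id for p in peak_seqs], occ_fg)
    pres_bg = motif_presence([p.peak_id for p in background], occ_bg)

    rows = []
    for m in motifs:
        ca = int(pres_fg[m.name].sum()) if m.name in pres_fg else 0
        cb = int(pres_bg[m.name].sum()) if m.name in pres_bg else 0
        p_bg = cb / n_bg
        if ca == 0 and cb == 0:
            pval = 1.0
        elif p_bg == 0.0:
            # background proportion zero: any presence is infinitely enriched
            pval = 0.0 if ca > 0 else 1.0
        else:
            pval = stats.binomtest(ca, n_fg, p_bg, alternative="greater").pvalue
        rows.append((m.name, m.family, ca, n_fg, cb, n_bg,
                     ca / n_fg, p_bg, pval))
    out = pd.DataFrame(
        rows,
        columns=["motif", "family", "count_a", "total_a", "count_b", "total_b",
                 "proportion_a", "proportion_b", "p_value"],
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def differential_motif_enrichment(
    presence_a: pd.DataFrame, presence_b: pd.DataFrame
) -> pd.DataFrame:
    """Two-sample test of equal proportions per motif, BH across motifs.

    For each motif, compares the proportion of peaks containing it in set
    a vs set b with a pooled two-proportion z-test (no continuity
    correction); two-sided p-values.  Positive statistic means a higher
    proportion in set a.
    """
    na, nb = len(presence_a), len(presence_b)
    if na == 0 or nb == 0:
        raise ValueError("differential enrichment requires two non-empty peak sets")
    motifs = sorted(set(presence_a.columns) | set(presence_b.columns))
    rows = []
    for m in motifs:
        ca = int(presence_a[m].sum()) if m in presence_a else 0
        cb = int(presence_b[m].sum()) if m in presence_b else 0
        pooled = (ca + cb) / (na + nb)
        if pooled in (0.0, 1.0):
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest([ca, cb], [na, nb], alternative="two-sided")
        rows.append((m, ca, na, cb, nb, ca / na, cb / nb, float(z), float(p)))
    out = pd.DataFrame(
        rows,
        columns=["motif", "count_a", "total_a", "count_b", "total_b",
                 "proportion_a", "proportion_b", "statistic", "p_value"],
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def motif_density_profile(
    occurrences: pd.DataFrame,
    n_peaks: int,
    window: int = 1000,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Summit-anchored motif density, in motifs per bp per 1000 peaks.

    Offsets within [-window/2, window/2) are binned; the density in a bin
    is count / (bin_size * n_peaks / 1000).
    """
    if n_peaks <= 0:
        raise ValueError("motif_density_profile requires at least one peak")
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    edges = np.arange(-half, half + bin_size, bin_size)
    offsets = occurrences["offset"].to_numpy()
    counts, _ = np.histogram(offsets, bins=edges)
    centers = edges[:-1] + bin_size / 2
    density = counts / (bin_size * n_peaks / 1000)
    return pd.DataFrame(
        {"bin_center": centers, "count": counts, "density": density}
    )


def cooccurrence_enrichment(presence: pd.DataFrame) -> pd.DataFrame:
    """Co-occurrence enrichment for every motif pair in a presence table.

    observed = number of peaks containing both motifs; expected =
    n1 * n2 / N under independence; enrichment = log2((observed + 1) /
    (expected + 1)).  Symmetric in the pair.
    """
    n = len(presence)
    if n == 0:
        raise ValueError("cooccurrence_enrichment requires at least one peak")
    cols = list(presence.columns)
    mat = presence.to_numpy(dtype=bool)
    counts = mat.sum(axis=0)
    rows = []
    for i, j in combinations(range(len(cols)), 2):
        obs = int(np.logical_and(mat[:, i], mat[:, j]).sum())
        exp = counts[i] * counts[j] / n
        enr = float(np.log2((obs + 1) / (exp + 1)))
        rows.append((cols[i], cols[j], obs, exp, enr))
    return pd.DataFrame(
        rows,
        columns=["motif_a", "motif_b", "observed", "expected", "log2_enrichment"],
    )


def differential_cooccurrence(
    presence_a: pd.DataFrame,
    presence_b: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Fisher's exact test on pair presence between two peak sets.

    For each motif pair the 2x2 table is (peaks with both motifs vs not) x
    (set a vs set b); two-sided p-values, BH across pairs.  The log2 ratio
    of pair proportions (a over b, +1 pseudocounts on counts) is reported
    as the effect direction.
    """
    na, nb = len(presence_a), len(presence_b)
    if na == 0 or nb == 0:
        raise ValueError("differential co-occurrence requires non-empty peak sets")
    if pairs is None:
        shared = sorted(set(presence_a.columns) & set(presence_b.columns))
        pairs = list(combinations(shared, 2))
    rows = []
    for m1, m2 in pairs:
        ca = int((presence_a[m1] & presence_a[m2]).sum())
        cb = int((presence_b[m1] & presence_b[m2]).sum())
        _, p = stats.fisher_exact([[ca, na - ca], [cb, nb - cb]])
        log2_ratio = float(
            np.log2(((ca + 1) / (na + 1)) / ((cb + 1) / (nb + 1)))
        )
        rows.append((m1, m2, ca, na, cb, nb, log2_ratio, float(p)))
    out = pd.DataFrame(
        rows,
        columns=["motif_a", "motif_b", "count_a", "total_a", "count_b",
                 "total_b", "log2_enrichment", "p_value"],
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def spacing_profile(
    anchors: pd.DataFrame,
    secondaries: pd.DataFrame,
    window: int = 1000,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Stranded density of secondary motifs around anchor motifs.

    For every anchor occurrence, secondary occurrences in the same peak
    are positioned relative to the anchor and the anchor's orientation:
    offsets are negated for minus-strand anchors, and the secondary strand
    is recorded as 'same' or 'opposite' relative to the anchor.  Self
    pairs (same motif, same position, same strand) are excluded.  Returns
    per-bin counts and densities (per bp per 1000 anchors) for each
    relative strand.
    """
    if len(anchors) == 0:
        raise ValueError("spacing_profile requires at least one anchor occurrence")
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    edges = np.arange(-half, half + bin_size, bin_size)
    n_anchors = len(anchors)
    rels: dict[str, list[float]] = {"same": [], "opposite": []}
    sec_by_peak = dict(tuple(secondaries.groupby("peak_id")))
    for a in anchors.itertuples(index=False):
        sub = sec_by_peak.get(a.peak_id)
        if sub is None:
            continue
        for s in sub.itertuples(index=False):
            if (
                s.motif == a.motif
                and s.offset == a.offset
                and s.strand == a.strand
            ):
                continue  # the anchor itself
            rel = s.offset - a.offset
            same = s.strand == a.strand
            if a.strand == "-":
                rel = -rel
            rels["same" if same else "opposite"].append(rel)

    frames = []
    for strand, offs in rels.items():
        counts, _ = np.histogram(np.asarray(offs, dtype=float), bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "bin_center": edges[:-1] + bin_size / 2,
                    "strand": strand,
                    "count": counts,
                    "density": counts / (bin_size * n_anchors / 1000),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# In-silico mutagenesis
# ---------------------------------------------------------------------------

def mutate_motif_sites(
    sequence: str, sites: Sequence[tuple[int, str]]
) -> str:
    """Edit homeodomain motif sites in a sequence.

    Each site is (offset, mode) where the sequence at ``offset`` must start
    with the TAAT homeodomain core.  mode='null' inactivates the site by
    mutating TAAT to TGGT; mode='q50' converts the 6-mer at the site to the
    Q50 motif TAATTA.  All other bases are untouched and length is
    preserved.
    """
    seq = list(sequence)
    for offset, mode in sites:
        core = "".join(seq[offset : offset + 4]).upper()
        if core != "TAAT":
            raise ValueError(
                f"site at offset {offset} does not start with TAAT (found {core!r})"
            )
        if mode == "null":
            seq[offset : offset + 4] = "TGGT"
        elif mode == "q50":
            if offset + 6 > len(seq):
                raise ValueError(f"q50 conversion at offset {offset} exceeds sequence")
            seq[offset : offset + 6] = "TAATTA"
        else:
            raise ValueError(f"unknown mutation mode {mode!r}")
    return "".join(seq)
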