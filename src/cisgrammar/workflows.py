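"""Composed analysis workflows on synthetic data with planted truth.

Each function runs one end-to-end recipe of the comparative grammar
analysis on generated data and reports summary metrics: the independence
null for motif co-occurrence, recovery of the planted photoreceptor /
bipolar grammar, calibration and power of the differential NB test,
contamination-filter recovery, the accessibility-expression quadrant
pipeline, and the bulk vs pseudo-bulk benchmark.  They are the package's
own reference experiments; both the test suite and the results script
drive them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import (
    DEFAULT_POPULATIONS,
    CountMatrix,
    SimulationConfig,
    classify_quadrants,
    cooccurrence_enrichment,
    differential_motif_enrichment,
    filter_contaminants,
    generate_atac_counts,
    generate_genome,
    generate_peak_sets,
    generate_rna_counts,
    generate_single_cell,
    generate_tss_annotations,
    load_motifs,
    motif_presence,
    nb_wald_test,
    pair_peaks_with_genes,
    peak_sequences,
    scan_motif_set,
)
from .intervals import PeakSet, assign_nearest_tss
from .pseudobulk import compare_bulk_pseudobulk, pseudobulk_counts


def independence_null_summary(
    seed: int, n_peaks: int = 2000, n_motifs: int = 32, density: float = 1.0
) -> dict:
    """Co-occurrence enrichment when motifs are planted independently.

    Presence of each of ``n_motifs`` synthetic motifs in each of
    ``n_peaks`` peaks is an independent Poisson(density) planting; under
    this independence model the log2((obs+1)/(exp+1)) enrichment should
    average to ~0 over all pairs.
    """
    rng = np.random.default_rng([int(seed), 101])
    presence = pd.DataFrame(
        rng.poisson(density, size=(n_peaks, n_motifs)) > 0,
        columns=[f"motif{i:02d}" for i in range(n_motifs)],
    )
    pairs = cooccurrence_enrichment(presence)
    return {
        "n_pairs": len(pairs),
        "mean_abs_log2_enrichment": float(
            pairs["log2_enrichment"].abs().mean()
        ),
    }


def grammar_recovery(seed: int, n_peaks_per_class: int = 400) -> pd.DataFrame:
    """Differential motif enrichment between planted cell-class peak sets.

    Generates the default grammar (K50 in both classes, Q50 only in
    photoreceptor-specific peaks, E-box enriched in bipolar-specific
    peaks), scans the shipped motif set and compares proportions between
    the photoreceptor-specific and bipolar-specific peaks.  Positive
    statistics point toward photoreceptors (set a).
    """
    cfg = SimulationConfig(
        genome_length=max(1_000_000, n_peaks_per_class * 4 * 400),
        n_peaks_per_class=n_peaks_per_class,
        seed=seed,
    )
    genome = generate_genome(cfg)
    peak_sets, _ = generate_peak_sets(cfg, genome)
    motifs = load_motifs()
    presence = {}
    for cat in ("photoreceptor", "bipolar"):
        seqs = peak_sequences(genome, peak_sets[cat])
        occ = scan_motif_set(seqs, motifs)
        presence[cat] = motif_presence([s.peak_id for s in seqs], occ)
    res = differential_motif_enrichment(
        presence["photoreceptor"], presence["bipolar"]
    )
    return res.set_index("motif")


def differential_test_calibration(
    seed: int,
    n_features: int = 2000,
    n_replicates: int = 4,
    planted_lfc: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Null calibration and planted-effect recovery of the NB Wald test.

    Null: features with a common mean across two groups of
    ``n_replicates`` samples; reports the raw-p rejection rate at
    ``alpha`` and the KS test against uniformity.  Recovery: 10% of
    features planted per direction at |log2FC| = ``planted_lfc`` (means
    >= 200); reports sensitivity and empirical FDR of the called set.
    """
    design = {
        f"{g}_rep{i}": g
        for g in ("photoreceptor", "bipolar")
        for i in range(n_replicates)
    }
    ids = [f"f{i:05d}" for i in range(n_features)]

    null_cfg = SimulationConfig(
        seed=seed, nb_mean_range=(200.0, 1000.0), planted_fraction=0.0
    )
    cm_null, _ = generate_atac_counts(
        ids, design, null_cfg, planted_signs={i: 0 for i in ids}
    )
    res_null = nb_wald_test(cm_null)
    pvals = res_null["p_value"].to_numpy()
    type1 = float((pvals < alpha).mean())
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)

    effect_cfg = SimulationConfig(
        seed=seed + 1, nb_mean_range=(200.0, 1000.0), planted_lfc=planted_lfc
    )
    signs = {
        f: (1 if i % 10 == 0 else (-1 if i % 10 == 1 else 0))
        for i, f in enumerate(ids)
    }
    cm_eff, truth = generate_atac_counts(
        ids, design, effect_cfg, planted_signs=signs
    )
    res_eff = nb_wald_test(cm_eff)
    planted = set(truth.planted_da)
    called = set(res_eff.index[res_eff["called"]])
    sensitivity = len(called & planted) / len(planted)
    empirical_fdr = (
        len(called - planted) / len(called) if called else 0.0
    )
    return {
        "type1_error": type1,
        "type1_nominal": alpha,
        "type1_se": float(np.sqrt(alpha * (1 - alpha) / n_features)),
        "ks_uniformity_p": ks_p,
        "sensitivity": float(sensitivity),
        "empirical_fdr": float(empirical_fdr),
        "n_planted": len(planted),
        "n_called": len(called),
    }


def contamination_recovery(
    seed: int, n_genes: int = 2500, n_contaminants: int = 60
) -> dict:
    """Recovery of planted photoreceptor contaminants by the fold filter.

    A contaminant is recovered when no final kept list still reports it as
    a called bipolar-enriched gene (either the filter removed it or the
    differential stage never listed it).  False removal is the fraction of
    truly bipolar-enriched planted genes struck by the filter.
    """
    cfg = SimulationConfig(
        seed=seed, n_contaminant_genes=n_contaminants,
        contamination_fraction=0.05,
    )
    genes = [f"g{i:05d}" for i in range(n_genes)]
    design = {
        f"{g}_rep{i}": g
        for g in ("rod", "blue_cone", "bipolar")
        for i in range(cfg.n_replicates)
    }
    cm, truth = generate_rna_counts(genes, design, cfg)
    de_tables = {
        pair: nb_wald_test(cm, contrast=pair)
        for pair in [
            ("bipolar", "rod"),
            ("bipolar", "blue_cone"),
            ("rod", "blue_cone"),
        ]
    }
    res = filter_contaminants(de_tables)
    surviving, removed = set(), set()
    for kr in res.values():
        kept = kr["kept"]
        surviving |= set(kept.index[(kept["log2fc"] > 0) & kept["called"]])
        removed |= set(kr["removed"].index)
    contaminants = truth.contaminant_genes
    true_bipolar = {g for g, s in truth.planted_de.items() if s == 1}
    return {
        "contaminant_recall": len(contaminants - surviving) / len(contaminants),
        "false_removal_rate": len(removed & true_bipolar) / len(true_bipolar),
        "n_contaminants": len(contaminants),
        "n_filter_removed": len(removed),
    }


def quadrant_pipeline_recovery(
    seed: int, n_peaks_per_class: int = 300
) -> dict:
    """End-to-end accessibility x expression quadrant classification.

    Generates peaks with planted class-specific accessibility, pairs each
    peak with its nearest-TSS gene, plants concordant expression for the
    differential peaks, runs both differential tests and the quadrant
    classifier, and scores recovery of the planted concordant labels.
    """
    cfg = SimulationConfig(
        genome_length=max(1_000_000, n_peaks_per_class * 4 * 400),
        n_peaks_per_class=n_peaks_per_class,
        seed=seed,
        planted_lfc=3.0,
    )
    genome = generate_genome(cfg)
    peak_sets, _ = generate_peak_sets(cfg, genome)
    cats = ("photoreceptor", "bipolar", "shared")
    combined = PeakSet(
        "retina", [iv for c in cats for iv in peak_sets[c]]
    )
    tss = generate_tss_annotations(peak_sets, cfg)
    assignments = assign_nearest_tss(combined, tss)

    peak_ids = [iv.name for iv in combined]
    atac_design = {
        f"{g}_rep{i}": g
        for g in ("photoreceptor", "bipolar")
        for i in range(cfg.n_replicates)
    }
    atac, atac_truth = generate_atac_counts(peak_ids, atac_design, cfg)
    da = nb_wald_test(atac)

    genes = [f"gene_{p}" for p in peak_ids]
    rna_design = {
        f"{g}_rep{i}": g
        for g in ("rod", "blue_cone", "bipolar")
        for i in range(cfg.n_replicates)
    }
    # concordant planting: genes of photoreceptor-accessible peaks are
    # photoreceptor-expressed (rna sign convention: +1 = bipolar-enriched)
    rna_signs = {f"gene_{p}": -s for p, s in atac_truth.planted_da.items()}
    rna, _ = generate_rna_counts(
        genes, rna_design, cfg, planted_signs=rna_signs
    )
    pooled = rna.groups.replace(
        {"rod": "photoreceptor", "blue_cone": "photoreceptor"}
    )
    rna_pooled = CountMatrix(counts=rna.counts, groups=pooled)
    de = nb_wald_test(rna_pooled, contrast=("photoreceptor", "bipolar"))

    pairs, excluded = pair_peaks_with_genes(assignments, da, de)
    classes = classify_quadrants(pairs)
    labels = classes.set_index("peak_id")["label"]
    expect = {
        p: ("concordant_class_a" if s > 0 else "concordant_class_b")
        for p, s in atac_truth.planted_da.items()
    }
    recovered = sum(labels.get(p) == lab for p, lab in expect.items())
    counts = classes["label"].value_counts().to_dict()
    return {
        "sensitivity": recovered / len(expect),
        "n_planted_concordant": len(expect),
        "label_counts": counts,
        "partition_ok": bool(sum(counts.values()) == len(pairs)),
        "n_excluded": len(excluded),
    }


def pseudobulk_benchmark(
    seed: int,
    n_runs: int = 100,
    n_genes: int = 1500,
    n_cells_per_cluster: int = 200,
    bulk_depth: float = 100.0,
    bulk_replicates: int = 2,
) -> dict:
    """Bulk vs pseudo-bulk correlation benchmark over seeded runs.

    Each run generates a clustered single-cell matrix, aggregates ON / OFF /
    pan-bipolar pseudo-bulk profiles, simulates matched bulk RNA samples
    whose group means are the size-weighted planted cluster means (scaled
    by ``bulk_depth`` to bulk sequencing scale), and asks whether every
    bulk population correlates best with its own pseudo-bulk.
    """
    genes = [f"g{i:05d}" for i in range(n_genes)]
    pops = {k: set(v) for k, v in DEFAULT_POPULATIONS.items()}
    wins = 0
    diag = []
    for run in range(n_runs):
        run_seed = (int(seed) + 7919 * run) % 2**31
        cfg = SimulationConfig(
            seed=run_seed, n_cells_per_cluster=n_cells_per_cluster
        )
        sc, truth = generate_single_cell(genes, cfg)
        pseudo = pseudobulk_counts(sc, pops)
        sizes = sc.clusters.value_counts()
        gm = {}
        for pop, members in pops.items():
            w = np.array([sizes[c] for c in sorted(members)], dtype=float)
            gm[pop] = truth.cluster_means[sorted(members)].to_numpy() @ (
                w / w.sum()
            )
        group_means = pd.DataFrame(gm, index=genes) * bulk_depth
        design = {
            f"{p}_rep{i}": p for p in pops for i in range(bulk_replicates)
        }
        bulk_cm, _ = generate_rna_counts(
            genes, design, cfg, group_means=group_means
        )
        bulk = pd.DataFrame(
            {
                p: bulk_cm.counts[
                    [s for s, g in design.items() if g == p]
                ].mean(axis=1)
                for p in pops
            }
        )
        table = compare_bulk_pseudobulk(bulk, pseudo)
        best = table.idxmax(axis=1)
        wins += int(all(best[p] == p for p in pops))
        diag.extend(float(table.loc[p, p]) for p in pops)
    return {
        "best_match_fraction": wins / n_runs,
        "n_runs": n_runs,
        "diag_correlation_min": float(np.min(diag)),
        "diag_correlation_max": float(np.max(diag)),
    }
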