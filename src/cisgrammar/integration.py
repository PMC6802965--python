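"""Integration of differential accessibility with differential expression.

Each differentially tested peak is paired (by nearest-TSS assignment) with
a gene and its differential-expression result, then classified by the
accessibility x expression quadrant scheme: peaks whose accessibility and
assigned-gene expression are both at least ``fold``-fold higher in the
same cell class (with FDR below threshold in both dimensions) are
*concordant* for that class; both-significant but opposite-direction peaks
are *discordant*; everything else is *shared_or_modest*.  The labels map
onto the usual scatter coloring: concordant class a / class b, gray for
shared-or-modest, black for discordant.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

LABELS = (
    "concordant_class_a",
    "concordant_class_b",
    "shared_or_modest",
    "discordant",
)


def pair_peaks_with_genes(
    assignments: pd.DataFrame,
    da_results: pd.DataFrame,
    de_results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join nearest-TSS assignments with DA and DE tables.

    ``assignments`` comes from :func:`cisgrammar.intervals.assign_nearest_tss`
    (columns peak_id, gene_id, ...); DA results are indexed by peak, DE
    results by gene.  Returns (pairs, excluded): peaks whose assigned gene
    has no expression record (or that have no assignment) are reported in
    ``excluded`` rather than imputed.
    """
    rows, excluded = [], []
    for r in assignments.itertuples(index=False):
        if (
            not r.assigned
            or r.peak_id not in da_results.index
            or r.gene_id not in de_results.index
        ):
            excluded.append((r.peak_id, r.gene_id))
            continue
        da = da_results.loc[r.peak_id]
        de = de_results.loc[r.gene_id]
        rows.append(
            (
                r.peak_id,
                r.gene_id,
                float(da["log2fc"]),
                float(da["fdr"]),
                float(de["log2fc"]),
                float(de["fdr"]),
            )
        )
    pairs = pd.DataFrame(
        rows,
        columns=["peak_id", "gene_id", "da_log2fc", "da_fdr", "de_log2fc", "de_fdr"],
    )
    excluded_df = pd.DataFrame(excluded, columns=["peak_id", "gene_id"])
    return pairs, excluded_df


def classify_quadrants(
    pairs: pd.DataFrame,
    fold: float = 4.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Quadrant labels for peak/gene pairs with DA and DE statistics.

    Positive log2 fold-changes point toward class a.  With the default
    fold = 4 the cut is |log2fc| >= 2 (inclusive) in both dimensions, plus
    FDR < ``fdr`` in both; concordant labels require agreement in sign,
    discordant requires both dimensions to pass in opposite directions,
    and everything else is shared_or_modest.
    """
    required = {"peak_id", "da_log2fc", "da_fdr", "de_log2fc", "de_fdr"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table lacks columns {sorted(missing)}")
    log2_fold = np.log2(fold)
    out = pairs.copy()
    da_pass = (out["da_log2fc"].abs() >= log2_fold) & (out["da_fdr"] < fdr)
    de_pass = (out["de_log2fc"].abs() >= log2_fold) & (out["de_fdr"] < fdr)
    same_sign = np.sign(out["da_log2fc"]) == np.sign(out["de_log2fc"])

    label = np.full(len(out), "shared_or_modest", dtype=object)
    both = (da_pass & de_pass).to_numpy()
    concordant = both & same_sign.to_numpy()
    discordant = both & ~same_sign.to_numpy()
    toward_a = (out["da_log2fc"] > 0).to_numpy()
    label[concordant & toward_a] = "concordant_class_a"
    label[concordant & ~toward_a] = "concordant_class_b"
    label[discordant] = "discordant"
    out["label"] = label
    return out


def expression_by_peak_class(
    classes: pd.DataFrame,
    expression: pd.DataFrame,
    gene_column: str = "gene_id",
) -> pd.DataFrame:
    """Summaries of assigned-gene expression per quadrant label.

    ``expression`` is genes x cell classes (normalized means).  For every
    (label, cell class) the count, median and quartiles of the expression
    of the genes assigned to peaks with that label are returned — the
    per-class expression comparison behind accessibility/expression
    correlation summaries.
    """
    if classes.empty:
        raise ValueError("no classified peaks supplied")
    rows = []
    for label, sub in classes.groupby("label"):
        genes = [g for g in sub[gene_column] if g in expression.index]
        for cls in expression.columns:
            vals = expression.loc[genes, cls].to_numpy(dtype=float)
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append((label, cls, len(vals), q1, med, q3))
    return pd.DataFrame(
        rows,
        columns=["label", "cell_class", "n", "q1", "median", "q3"],
    )
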