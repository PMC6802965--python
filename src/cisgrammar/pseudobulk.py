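"""Pseudo-bulk aggregation of clustered single-cell counts.

Single-cell profiles with cluster assignments are pooled into bulk-like
expression vectors per population of interest (a population is a set of
clusters, e.g. the ON bipolar types), rescaled to match bulk totals, and
compared to bulk profiles by Pearson correlation of log2(x + 1) values.
The weighted average over clusters uses cluster cell counts as weights,
which is exactly the plain mean over all member cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class SingleCellMatrix:
    """Genes x cells (normalized) counts with a cluster label per cell."""

    counts: pd.DataFrame
    clusters: pd.Series

    def __post_init__(self):
        self.clusters = self.clusters.reindex(self.counts.columns)
        if self.clusters.isna().any():
            missing = list(self.clusters[self.clusters.isna()].index)
            raise ValueError(f"cells {missing} have no cluster label")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    def cells_in(self, clusters: frozenset[str] | set[str]) -> list[str]:
        mask = self.clusters.isin(clusters)
        return list(self.clusters[mask].index)


def validate_population_map(
    sc: SingleCellMatrix, populations: Mapping[str, frozenset[str] | set[str]]
) -> None:
    present = set(sc.clusters.unique())
    for name, members in populations.items():
        if not members:
            raise ValueError(f"population {name!r} has no clusters")
        unknown = set(members) - present
        if unknown:
            raise ValueError(
                f"population {name!r} references unknown clusters {sorted(unknown)}"
            )


def pseudobulk_counts(
    sc: SingleCellMatrix,
    populations: Mapping[str, frozenset[str] | set[str]],
) -> pd.DataFrame:
    """Per-population pseudo-bulk vectors (genes x populations).

    Each vector is the average of counts over all cells belonging to the
    population's clusters — a cluster-size-weighted average of cluster
    means.  Order of cells is immaterial.
    """
    validate_population_map(sc, populations)
    cols = {}
    for name, members in populations.items():
        cells = sc.cells_in(members)
        if not cells:
            raise ValueError(f"population {name!r} contains no cells")
        cols[name] = sc.counts[cells].mean(axis=1)
    return pd.DataFrame(cols)


def rescale_to_bulk(pseudo: pd.Series, bulk: pd.Series) -> pd.Series:
    """Scale a pseudo-bulk vector so its total matches the bulk total.

    A single multiplicative factor over the shared gene universe; relative
    proportions (and hence correlations) are unchanged.
    """
    shared = pseudo.index.intersection(bulk.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between pseudo-bulk and bulk")
    total = float(pseudo.loc[shared].sum())
    if total <= 0:
        raise ValueError("pseudo-bulk vector sums to zero on shared genes")
    factor = float(bulk.loc[shared].sum()) / total
    return pseudo * factor


def compare_bulk_pseudobulk(
    bulk: pd.DataFrame, pseudo: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of log2(x+1) profiles, bulk x pseudo populations.

    Rows are bulk populations, columns pseudo-bulk populations; computed
    over the shared gene universe.
    """
    shared = bulk.index.intersection(pseudo.index)
    if len(shared) < 2:
        raise ValueError("need at least two shared genes for correlation")
    lb = np.log2(bulk.loc[shared].to_numpy(dtype=float) + 1.0)
    lp = np.log2(pseudo.loc[shared].to_numpy(dtype=float) + 1.0)
    if (lb.std(axis=0) == 0).any() or (lp.std(axis=0) == 0).any():
        raise ValueError("constant expression vector; correlation undefined")
    table = np.empty((bulk.shape[1], pseudo.shape[1]))
    for i in range(bulk.shape[1]):
        for j in range(pseudo.shape[1]):
            table[i, j] = np.corrcoef(lb[:, i], lp[:, j])[0, 1]
    return pd.DataFrame(table, index=bulk.columns, columns=pseudo.columns)
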