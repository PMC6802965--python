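"""Rule-based removal of photoreceptor contamination from DE results.

FACS-sorted bipolar populations carry a low level of photoreceptor
carry-over, so genes that are actually photoreceptor-specific can appear
"bipolar-enriched" when the bipolar population is compared against the
*other* photoreceptor type.  The filter removes, from each
bipolar-enriched gene list, genes that are

* strongly specific (> ``specificity_fold``, strict, default 16) to the
  alternate photoreceptor type relative to the comparison photoreceptor,
  and
* more highly expressed (>= ``enrichment_fold``, inclusive, default 4) in
  that alternate photoreceptor than in the bipolar population.

For comparisons between two bipolar populations (ON vs OFF), a gene
enriched in one bipolar population is removed when it is
> ``specificity_fold`` higher in *both* photoreceptor types than in that
population.

Fold ratios are computed on normalized group means with a 0.5 pseudocount.
Removed genes are always reported with their triggering ratios, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .diffcounts import LFC_PSEUDOCOUNT

Comparison = tuple[str, str]


@dataclass(frozen=True)
class FilterRule:
    """Fold-change thresholds of the contamination filter."""

    specificity_fold: float = 16.0
    enrichment_fold: float = 4.0

    def __post_init__(self):
        if self.specificity_fold <= 1 or self.enrichment_fold <= 1:
            raise ValueError("filter thresholds must exceed 1")


def _mean_lookup(
    de_tables: Mapping[Comparison, pd.DataFrame], group_x: str, group_y: str
) -> tuple[pd.Series, pd.Series]:
    """Normalized mean vectors (x, y) from whichever table compares them."""
    if (group_x, group_y) in de_tables:
        t = de_tables[(group_x, group_y)]
        return t["mean_a"], t["mean_b"]
    if (group_y, group_x) in de_tables:
        t = de_tables[(group_y, group_x)]
        return t["mean_b"], t["mean_a"]
    raise KeyError(
        f"required comparison ({group_x} vs {group_y}) missing from de_tables"
    )


def _ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    return (num + LFC_PSEUDOCOUNT) / (den + LFC_PSEUDOCOUNT)


def filter_contaminants(
    de_tables: Mapping[Comparison, pd.DataFrame],
    rule: FilterRule = FilterRule(),
    bipolar_groups: tuple[str, ...] = ("bipolar",),
    photoreceptor_groups: tuple[str, str] = ("rod", "blue_cone"),
    targets: list[Comparison] | None = None,
) -> dict[Comparison, dict[str, pd.DataFrame]]:
    """Apply the contamination filter to the target comparisons.

    ``de_tables`` maps (group_a, group_b) to a differential-result frame
    indexed by gene with columns including log2fc (a over b), mean_a,
    mean_b and called.  ``targets`` selects which comparisons to filter; by
    default every comparison involving a bipolar group is a target, with
    the remaining tables serving as ratio lookups.  For each target, the
    genes called enriched on the bipolar side are screened; the returned
    mapping gives, per comparison, 'kept' and 'removed' frames (removed
    carries the triggering fold ratios).  Required cross-comparison tables
    (e.g. rod vs blue cone) must be present, otherwise the missing one is
    named in the error.
    """
    out: dict[Comparison, dict[str, pd.DataFrame]] = {}
    pr = photoreceptor_groups
    if targets is None:
        targets = [
            pair for pair in de_tables
            if pair[0] in bipolar_groups or pair[1] in bipolar_groups
        ]
    missing = [t for t in targets if t not in de_tables]
    if missing:
        raise KeyError(f"target comparisons {missing} missing from de_tables")
    for ga, gb in targets:
        table = de_tables[(ga, gb)]
        a_bip, b_bip = ga in bipolar_groups, gb in bipolar_groups
        a_pr, b_pr = ga in pr, gb in pr
        if a_bip and b_pr:
            out[(ga, gb)] = _filter_vs_photoreceptor(
                table, ga, gb, de_tables, rule, pr, bipolar_side="a"
            )
        elif b_bip and a_pr:
            out[(ga, gb)] = _filter_vs_photoreceptor(
                table, gb, ga, de_tables, rule, pr, bipolar_side="b"
            )
        elif a_bip and b_bip:
            out[(ga, gb)] = _filter_bipolar_pair(
                table, ga, gb, de_tables, rule, pr
            )
    return out


def _filter_vs_photoreceptor(
    table: pd.DataFrame,
    bipolar: str,
    photoreceptor: str,
    de_tables: Mapping[Comparison, pd.DataFrame],
    rule: FilterRule,
    pr: tuple[str, str],
    bipolar_side: str,
) -> dict[str, pd.DataFrame]:
    """Bipolar vs photoreceptor comparison: screen the bipolar-enriched side.

    A gene enriched in the bipolar population relative to photoreceptor P
    is suspect when the alternate photoreceptor Q expresses it
    > specificity_fold above P and >= enrichment_fold above the bipolar
    population — the signature of Q-type carry-over.
    """
    alternate = pr[0] if photoreceptor == pr[1] else pr[1]
    q_mean, p_mean = _mean_lookup(de_tables, alternate, photoreceptor)
    q_mean2, bip_mean = _mean_lookup(de_tables, alternate, bipolar)

    enriched_in_bip = (
        table["log2fc"] > 0 if bipolar_side == "a" else table["log2fc"] < 0
    )
    candidates = table.index[enriched_in_bip & table["called"]]
    spec_ratio = _ratio(q_mean, p_mean).reindex(candidates)
    enr = _ratio(q_mean2, bip_mean).reindex(candidates)
    flag = (spec_ratio > rule.specificity_fold) & (enr >= rule.enrichment_fold)
    removed_ids = candidates[flag.fillna(False)]

    removed = table.loc[removed_ids].copy()
    removed["specificity_ratio"] = spec_ratio.loc[removed_ids]
    removed["enrichment_ratio"] = enr.loc[removed_ids]
    removed["contaminant_source"] = alternate
    kept = table.drop(index=removed_ids)
    return {"kept": kept, "removed": removed}


def _filter_bipolar_pair(
    table: pd.DataFrame,
    ga: str,
    gb: str,
    de_tables: Mapping[Comparison, pd.DataFrame],
    rule: FilterRule,
    pr: tuple[str, str],
) -> dict[str, pd.DataFrame]:
    """ON vs OFF style comparison: screen both enriched sides.

    A gene enriched in bipolar population X is removed when both
    photoreceptor types exceed X by > specificity_fold.
    """
    removed_frames = []
    removed_ids_all = []
    for side, bip in (("a", ga), ("b", gb)):
        enriched = (
            table["log2fc"] > 0 if side == "a" else table["log2fc"] < 0
        )
        candidates = table.index[enriched & table["called"]]
        ratios = {}
        flag = pd.Series(True, index=candidates)
        for q in pr:
            q_mean, bip_mean = _mean_lookup(de_tables, q, bip)
            r = _ratio(q_mean, bip_mean).reindex(candidates)
            ratios[q] = r
            flag &= r > rule.specificity_fold
        ids = candidates[flag.fillna(False)]
        sub = table.loc[ids].copy()
        for q in pr:
            sub[f"ratio_{q}"] = ratios[q].loc[ids]
        sub["enriched_in"] = bip
        removed_frames.append(sub)
        removed_ids_all.extend(ids)
    removed = pd.concat(removed_frames) if removed_frames else table.iloc[:0]
    kept = table.drop(index=removed_ids_all)
    return {"kept": kept, "removed": removed}
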