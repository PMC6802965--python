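"""Interval algebra for open-chromatin peak sets.

Peaks are genomic intervals in BED convention (0-based, half-open) with a
summit recorded as an offset from the interval start.  This module provides
the set operations the comparative accessibility analysis needs: merging
peak calls from many samples into a union, classifying peaks as promoters
or enhancers relative to annotated transcription start sites (TSS),
assigning each peak to its nearest TSS, computing overlap fractions between
peak sets, and filtering a peak set down to tissue-specific peaks.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Promoter window around a TSS (strand-oriented): 1000 bp upstream through
# 100 bp downstream, both bounds inclusive.
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with a summit offset.

    ``summit`` is measured from ``start`` and must lie inside the interval.
    """

    chrom: str
    start: int
    end: int
    summit: int = 0
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.name or ''} "
                f"{self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )
        if not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"malformed interval {self.name or ''} "
                f"{self.chrom}:{self.start}-{self.end}: summit {self.summit} "
                "outside interval"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def summit_pos(self) -> int:
        """Absolute genomic position of the summit."""
        return self.start + self.summit

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TssAnnotation:
    """A transcription start site with its gene identifier and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"TSS position for {self.gene_id} must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand for {self.gene_id} must be + or -")


@dataclass
class PeakSet:
    """A labelled collection of peaks, kept sorted by (chrom, start)."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        seen = set()
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                raise ValueError(f"duplicate interval {key} in peak set {self.label}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "summit": [iv.summit for iv in self.intervals],
            }
        )


# ---------------------------------------------------------------------------
# BED / TSV input-output
# ---------------------------------------------------------------------------

def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a peak set as BED6 plus a seventh summit-offset column."""
    df = peaks.to_frame()
    df["score"] = 0
    df = df[["chrom", "start", "end", "name", "score", "strand", "summit"]]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read BED (3-6 columns, optional seventh summit column) into a PeakSet.

    When no summit column is present the summit defaults to the midpoint.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    intervals = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if ncol > 3 else ""
        strand = str(row[5]) if ncol > 5 and str(row[5]) in "+-." else "."
        summit = int(row[6]) if ncol > 6 else (end - start) // 2
        intervals.append(GenomicInterval(chrom, start, end, summit, strand, name))
    return PeakSet(label or Path(path).stem, intervals)


def read_tss(path: str | Path) -> list[TssAnnotation]:
    """Read a 4-column TSV (gene_id, chrom, position, strand) of TSS."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "chrom", "tss", "strand"]
    )
    return [
        TssAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_tss(tss: Sequence[TssAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tss],
            "chrom": [t.chrom for t in tss],
            "tss": [t.tss for t in tss],
            "strand": [t.strand for t in tss],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def merge_peak_union(sets: Iterable[PeakSet], label: str = "union") -> PeakSet:
    """Merge peak sets into the minimal disjoint union of intervals.

    Any two input intervals that share at least one base are merged.  The
    summit of a merged interval is its midpoint, and its name records the
    labels of every contributing set (sorted, comma-joined).
    """
    sets = list(sets)
    if not sets or all(len(s) == 0 for s in sets):
        raise ValueError("merge_peak_union requires at least one non-empty peak set")

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for s in sets:
        for iv in s:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, s.label))

    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        records = sorted(by_chrom[chrom])
        cur_start, cur_end, labels = records[0][0], records[0][1], {records[0][2]}
        idx = 0
        for start, end, lab in records[1:]:
            if start < cur_end:  # >=1 bp shared
                cur_end = max(cur_end, end)
                labels.add(lab)
            else:
                merged.append(
                    _union_interval(chrom, cur_start, cur_end, labels, idx)
                )
                idx += 1
                cur_start, cur_end, labels = start, end, {lab}
        merged.append(_union_interval(chrom, cur_start, cur_end, labels, idx))
    return PeakSet(label, merged)


def _union_interval(chrom, start, end, labels, idx) -> GenomicInterval:
    return GenomicInterval(
        chrom=chrom,
        start=start,
        end=end,
        summit=(end - start) // 2,
        strand=".",
        name=",".join(sorted(labels)),
    )


def classify_promoter_enhancer(
    peaks: PeakSet,
    tss: Sequence[TssAnnotation],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.Series:
    """Label each peak 'promoter' or 'enhancer' by its summit position.

    A peak is a promoter when its summit lies within [tss - upstream,
    tss + downstream] of a plus-strand TSS, or the mirrored window
    [tss - downstream, tss + upstream] of a minus-strand TSS (bounds
    inclusive).  All other peaks are enhancers (TSS-distal).  With no TSS
    every peak is an enhancer.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    for t in tss:
        if t.strand == "+":
            lo, hi = t.tss - upstream, t.tss + downstream
        else:
            lo, hi = t.tss - downstream, t.tss + upstream
        windows.setdefault(t.chrom, []).append((lo, hi))

    # Sweep with sorted window starts and a running prefix-max of window ends.
    starts_ends: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ws in windows.items():
        ws.sort()
        starts = [w[0] for w in ws]
        ends = list(np.maximum.accumulate([w[1] for w in ws]))
        starts_ends[chrom] = (starts, ends)

    labels = []
    index = []
    for i, iv in enumerate(peaks):
        pos = iv.summit_pos
        label = "enhancer"
        if iv.chrom in starts_ends:
            starts, ends = starts_ends[iv.chrom]
            j = bisect.bisect_right(starts, pos) - 1
            if j >= 0 and ends[j] >= pos:
                label = "promoter"
        labels.append(label)
        index.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
    return pd.Series(labels, index=index, name="class")


def assign_nearest_tss(
    peaks: PeakSet, tss: Sequence[TssAnnotation]
) -> pd.DataFrame:
    """Assign each peak to its nearest TSS by summit-to-TSS distance.

    Returns a frame with columns peak_id, gene_id, distance (summit minus
    TSS position, signed in genomic orientation).  Ties on absolute
    distance go to the lexicographically smaller gene_id.  Peaks on a
    chromosome without any TSS get gene_id = NA and are flagged
    ``assigned = False`` rather than dropped.
    """
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for t in tss:
        per_chrom.setdefault(t.chrom, []).append((t.tss, t.gene_id))
    for chrom in per_chrom:
        per_chrom[chrom].sort()

    rows = []
    for iv in peaks:
        peak_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        entries = per_chrom.get(iv.chrom)
        if not entries:
            rows.append((peak_id, pd.NA, np.nan, False))
            continue
        pos = iv.summit_pos
        positions = [e[0] for e in entries]
        j = bisect.bisect_left(positions, pos)
        # candidate indices straddling the summit
        cand = [k for k in (j - 1, j) if 0 <= k < len(entries)]
        best = min(abs(entries[k][0] - pos) for k in cand)
        # expand to all entries at the minimal absolute distance
        winners = []
        for k in range(min(cand), -1, -1):
            if abs(entries[k][0] - pos) == best:
                winners.append(entries[k])
            elif entries[k][0] < pos - best:
                break
        for k in range(max(cand), len(entries)):
            if abs(entries[k][0] - pos) == best:
                winners.append(entries[k])
            elif entries[k][0] > pos + best:
                break
        winners = [w for k, w in enumerate(winners) if w not in winners[:k]]
        tss_pos, gene = min(winners, key=lambda w: w[1])
        rows.append((peak_id, gene, pos - tss_pos, True))
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "distance", "assigned"]
    )


def _merged_tuples(peaks: PeakSet) -> dict[str, tuple[list[int], list[int]]]:
    """Disjoint (starts, ends) per chromosome for fast overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s < ce:
                ce = max(ce, e)
            else:
                starts.append(cs)
                ends.append(ce)
                cs, ce = s, e
        starts.append(cs)
        ends.append(ce)
        out[chrom] = (starts, ends)
    return out


def _overlaps_any(
    iv: GenomicInterval, merged: dict[str, tuple[list[int], list[int]]]
) -> bool:
    if iv.chrom not in merged:
        return False
    starts, ends = merged[iv.chrom]
    j = bisect.bisect_right(starts, iv.start) - 1
    if j >= 0 and ends[j] > iv.start:
        return True
    j += 1
    return j < len(starts) and starts[j] < iv.end


def overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of intervals in ``a`` overlapping (>=1 bp) any interval in ``b``."""
    if len(a) == 0:
        raise ValueError("overlap_fraction is undefined for an empty query set")
    if len(b) == 0:
        return 0.0
    merged = _merged_tuples(b)
    hits = sum(_overlaps_any(iv, merged) for iv in a)
    return hits / len(a)


def filter_tissue_specific(
    target: PeakSet, controls: Sequence[PeakSet]
) -> PeakSet:
    """Retain target peaks overlapping no control peak (>=1 bp excludes).

    This is the tissue-specificity filter: keep regions accessible in the
    cell class of interest but not in any of the control tissues.  With no
    controls it is the identity.
    """
    controls = [c for c in controls if len(c) > 0]
    if not controls:
        return PeakSet(target.label, list(target.intervals))
    merged = [_merged_tuples(c) for c in controls]
    kept = [
        iv for iv in target if not any(_overlaps_any(iv, m) for m in merged)
    ]
    return PeakSet(target.label, kept)
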