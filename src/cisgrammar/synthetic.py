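"""Synthetic data with planted ground truth for the whole pipeline.

Every input the analysis consumes can be generated here with a known
answer: a random genome with motif instances planted at class-specific
densities, peak sets per cell class and control tissue, TSS annotations
pairing each peak with a gene, negative-binomial count matrices with
planted differential accessibility/expression and planted photoreceptor
contamination of bipolar samples, and a clustered single-cell matrix with
matched bulk profiles.

The planted grammar mirrors the comparative photoreceptor/bipolar design:
K50 homeodomain motifs are planted in the peaks of both cell classes,
Q50 motifs only in photoreceptor-specific peaks, E-boxes predominantly in
bipolar-specific peaks, and CTCF motifs in shared/ubiquitous peaks.

All generators are pure functions of (config, seed): the run seed is
combined with a per-stage constant so each stage has an independent,
reproducible stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffcounts import CountMatrix
from .intervals import GenomicInterval, PeakSet, TssAnnotation
from .motifs import IUPAC, PeakSequence, load_motifs, reverse_complement
from .pseudobulk import SingleCellMatrix

# Peak categories: the two cell classes, peaks shared between them, and a
# control (non-retinal) tissue.
CELL_CLASSES = ("photoreceptor", "bipolar")
CATEGORIES = ("photoreceptor", "bipolar", "shared", "control")

# Expected planted occurrences per peak, per motif family and category.
DEFAULT_DENSITIES: dict[str, dict[str, float]] = {
    "K50_HD": {"photoreceptor": 2.0, "bipolar": 2.0, "shared": 2.0, "control": 0.0},
    "Q50_HD": {"photoreceptor": 1.5, "bipolar": 0.0, "shared": 0.0, "control": 0.0},
    "Ebox": {"photoreceptor": 0.3, "bipolar": 1.5, "shared": 0.5, "control": 0.0},
    "CTCF": {"photoreceptor": 0.0, "bipolar": 0.0, "shared": 1.5, "control": 1.5},
}

# Bipolar-cell cluster labels in the single-cell reference, grouped into
# the ON / OFF populations used for pseudo-bulk comparison.
ON_CLUSTERS = ("RBC", "BC5A", "BC5C", "BC5D", "BC6", "BC7", "BC8_BC9")
OFF_CLUSTERS = ("BC1A", "BC1B", "BC2", "BC3A", "BC3B", "BC4")
DEFAULT_POPULATIONS: dict[str, frozenset[str]] = {
    "ON": frozenset(ON_CLUSTERS),
    "OFF": frozenset(OFF_CLUSTERS),
    "panBC": frozenset(ON_CLUSTERS + OFF_CLUSTERS),
}

_STAGES = {"genome": 0, "peaks": 1, "atac": 2, "rna": 3, "single_cell": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults follow the structure of the real comparative design: two cell
    classes plus shared and control peak categories, negative-binomial
    counts (variance = mu + dispersion * mu^2) with four replicates per
    group, a planted two-to-eight-fold effect for differential features,
    and 5% photoreceptor contamination of bipolar RNA samples.
    """

    genome_length: int = 1_000_000
    n_peaks_per_class: int = 500
    peak_width: int = 200
    motif_densities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            fam: dict(cats) for fam, cats in DEFAULT_DENSITIES.items()
        }
    )
    background_composition: tuple[float, float, float, float] = (
        0.25, 0.25, 0.25, 0.25,
    )
    nb_mean_range: tuple[float, float] = (50.0, 1000.0)
    nb_dispersion: float = 0.05
    planted_lfc: float = 3.0
    planted_fraction: float = 0.2
    contamination_fraction: float = 0.05
    n_contaminant_genes: int = 50
    n_replicates: int = 4
    n_cells_per_cluster: int = 200
    tss_offset: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("n_peaks_per_class", "peak_width", "n_replicates",
                     "n_cells_per_cluster", "n_contaminant_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not math.isclose(sum(self.background_composition), 1.0, abs_tol=1e-9):
            raise ValueError("background_composition must sum to 1")
        if any(f < 0 for f in self.background_composition):
            raise ValueError("background_composition must be non-negative")
        for fam, cats in self.motif_densities.items():
            if any(d < 0 for d in cats.values()):
                raise ValueError(f"negative motif density for family {fam}")
        if not 0 <= self.contamination_fraction:
            raise ValueError("contamination_fraction must be >= 0")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Read a key=value config file (scalar fields only, '#' comments)."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if "," in value:
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("nb_dispersion", "planted_lfc", "planted_fraction",
                         "contamination_fraction"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset.

    Each generator fills only the fields it plants; ``planted_motifs`` has
    columns (peak_id, family, motif, offset, strand) with offsets relative
    to the peak summit.
    """

    planted_motifs: pd.DataFrame | None = None
    planted_da: dict[str, int] = field(default_factory=dict)
    planted_de: dict[str, int] = field(default_factory=dict)
    contaminant_genes: set[str] = field(default_factory=set)
    cluster_means: pd.DataFrame | None = None


class ReferenceSequences:
    """Mutable named sequences over {A,C,G,T} with FASTA input/output."""

    def __init__(self, sequences: Mapping[str, str | bytearray]):
        self._seqs: dict[str, bytearray] = {
            chrom: bytearray(str(s).upper().encode())
            if not isinstance(s, bytearray) else s
            for chrom, s in sequences.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom].decode()

    def subsequence(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end].decode()

    def set_subsequence(self, chrom: str, start: int, seq: str) -> None:
        self._seqs[chrom][start : start + len(seq)] = seq.encode()

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self[chrom]), id=chrom, description="")
            for chrom in self.chroms
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReferenceSequences":
        return cls(
            {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        )


# ---------------------------------------------------------------------------
# Genome and peaks
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> ReferenceSequences:
    """A single random chromosome with the configured base composition."""
    rng = _stage_rng(config.seed, "genome")
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"),
        size=config.genome_length,
        p=np.asarray(config.background_composition),
    )
    return ReferenceSequences({"chr1": bytearray(bases.tobytes())})


def _resolve_iupac(consensus: str, rng: np.random.Generator) -> str:
    """A concrete instance of an IUPAC consensus (degenerate codes sampled)."""
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
        for c in consensus
    )


def generate_peak_sets(
    config: SimulationConfig, genome: ReferenceSequences
) -> tuple[dict[str, PeakSet], SyntheticTruth]:
    """Lay out non-overlapping peaks per category and plant motifs.

    The genome is modified in place: for each peak, per-family Poisson
    numbers of motif instances are written at uniform positions within the
    central 80% of the peak (non-overlapping within a peak), on random
    strands.  The truth records every planting.  Summits are peak
    midpoints.
    """
    rng = _stage_rng(config.seed, "peaks")
    w = config.peak_width
    step = 2 * w
    n_total = config.n_peaks_per_class * len(CATEGORIES)
    chrom = genome.chroms[0]
    if n_total * step > genome.length(chrom):
        raise ValueError(
            f"{n_total} peaks of width {w} (stride {step}) exceed genome "
            f"capacity {genome.length(chrom)}"
        )

    motif_models = {m.name: m for m in load_motifs()}
    for fam in config.motif_densities:
        if fam not in motif_models:
            raise ValueError(f"motif density given for unknown motif {fam!r}")

    labels = np.repeat(CATEGORIES, config.n_peaks_per_class)
    rng.shuffle(labels)

    intervals: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORIES}
    counters = {c: 0 for c in CATEGORIES}
    truth_rows = []
    margin = max(1, int(round(0.1 * w)))

    for slot, cat in enumerate(labels):
        start = slot * step
        idx = counters[cat]
        counters[cat] += 1
        peak_id = f"{cat}_{idx:05d}"
        summit = w // 2
        intervals[cat].append(
            GenomicInterval(chrom, start, start + w, summit, ".", peak_id)
        )
        occupied: list[tuple[int, int]] = []
        for motif_name, cats in config.motif_densities.items():
            rate = cats.get(cat, 0.0)
            if rate <= 0:
                continue
            model = motif_models[motif_name]
            k = rng.poisson(rate)
            for _ in range(k):
                instance = _resolve_iupac(model.consensus, rng)
                m = len(instance)
                lo, hi = margin, w - margin - m
                if hi < lo:
                    continue
                for _try in range(50):
                    pos = int(rng.integers(lo, hi + 1))
                    if all(pos + m <= s or pos >= e for s, e in occupied):
                        break
                else:
                    continue  # no room left in this peak; planting skipped
                occupied.append((pos, pos + m))
                strand = "+" if rng.integers(2) == 0 else "-"
                written = instance if strand == "+" else reverse_complement(instance)
                genome.set_subsequence(chrom, start + pos, written)
                truth_rows.append(
                    (peak_id, model.family, motif_name, pos - summit, strand)
                )

    peak_sets = {cat: PeakSet(cat, ivs) for cat, ivs in intervals.items()}
    truth = SyntheticTruth(
        planted_motifs=pd.DataFrame(
            truth_rows, columns=["peak_id", "family", "motif", "offset", "strand"]
        )
    )
    return peak_sets, truth


def peak_sequences(
    genome: ReferenceSequences, peaks: PeakSet
) -> list[PeakSequence]:
    """Extract summit-anchored sequences for a peak set."""
    return [
        PeakSequence(
            iv.name or f"{iv.chrom}:{iv.start}-{iv.end}",
            genome.subsequence(iv.chrom, iv.start, iv.end),
            iv.summit,
        )
        for iv in peaks
    ]


def generate_tss_annotations(
    peak_sets: Mapping[str, PeakSet], config: SimulationConfig
) -> list[TssAnnotation]:
    """One gene TSS just downstream of every cell-class or shared peak.

    Gene ids are 'gene_<peak_id>', so each peak's nearest TSS is its own
    gene; this pins the peak-to-gene assignment for integration tests.
    """
    tss = []
    for cat, peaks in peak_sets.items():
        if cat == "control":
            continue
        for iv in peaks:
            tss.append(
                TssAnnotation(
                    f"gene_{iv.name}", iv.chrom, iv.end + config.tss_offset, "+"
                )
            )
    return tss


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _validate_design(design: Mapping[str, str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sample, group in design.items():
        groups.setdefault(group, []).append(sample)
    thin = [g for g, ss in groups.items() if len(ss) < 2]
    if thin:
        raise ValueError(
            f"groups {thin} have fewer than 2 replicates; "
            "dispersion is unidentifiable"
        )
    return groups


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, variance = mean + dispersion * mean^2) integer draws."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion < 1e-10:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _planted_signs_from_ids(
    feature_ids: Sequence[str], contrast: tuple[str, str]
) -> dict[str, int]:
    signs = {}
    for fid in feature_ids:
        if fid.startswith(contrast[0]):
            signs[fid] = 1
        elif fid.startswith(contrast[1]):
            signs[fid] = -1
        else:
            signs[fid] = 0
    return signs


def generate_atac_counts(
    feature_ids: Sequence[str],
    design: Mapping[str, str],
    config: SimulationConfig,
    planted_signs: Mapping[str, int] | None = None,
    contrast: tuple[str, str] = ("photoreceptor", "bipolar"),
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB accessibility counts with planted differential peaks.

    ``planted_signs`` maps features to +1 (more accessible in
    ``contrast[0]``), -1 (more accessible in ``contrast[1]``) or 0 (null);
    when omitted, signs are read from the feature-id prefix as produced by
    :func:`generate_peak_sets` (photoreceptor_* / bipolar_* peaks are
    differential toward their class, everything else null).  Planted
    features have expected |log2 fold-change| equal to ``planted_lfc``,
    split symmetrically around a log-uniform base mean; null features share
    one mean across groups.  Samples get mild random depth factors.
    """
    groups = _validate_design(design)
    for g in contrast:
        if g not in groups:
            raise ValueError(f"contrast group {g!r} absent from design")
    rng = _stage_rng(config.seed, "atac")
    if planted_signs is None:
        planted_signs = _planted_signs_from_ids(feature_ids, contrast)

    n = len(feature_ids)
    lo, hi = config.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    signs = np.array([planted_signs.get(f, 0) for f in feature_ids])
    half = config.planted_lfc / 2.0
    samples = list(design)
    depth = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(samples)))

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        g = design[sample]
        if g == contrast[0]:
            mu = base * np.power(2.0, signs * half)
        elif g == contrast[1]:
            mu = base * np.power(2.0, -signs * half)
        else:
            mu = base
        counts[:, j] = _nb_draw(rng, mu * depth[j], config.nb_dispersion)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=list(feature_ids), columns=samples),
        groups=pd.Series(dict(design)),
    )
    truth = SyntheticTruth(
        planted_da={f: int(s) for f, s in zip(feature_ids, signs) if s != 0}
    )
    return cm, truth


def generate_rna_counts(
    gene_ids: Sequence[str],
    design: Mapping[str, str],
    config: SimulationConfig,
    planted_signs: Mapping[str, int] | None = None,
    bipolar_group: str = "bipolar",
    photoreceptor_groups: tuple[str, str] = ("rod", "blue_cone"),
    group_means: pd.DataFrame | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB expression counts with planted DE genes and contamination.

    Planted genes (sign +1) are higher in the bipolar group than in both
    photoreceptor groups by ``planted_lfc`` log2 units (sign -1 mirrored).
    A further ``n_contaminant_genes`` null genes are made strongly specific
    to one photoreceptor type (64-fold above the other photoreceptor, with
    no intrinsic bipolar expression); bipolar samples receive
    ``contamination_fraction`` times that photoreceptor mean — emulating
    low-level photoreceptor carry-over in sorted bipolar populations.

    ``group_means`` (genes x groups) overrides all mean construction, for
    simulations that need externally matched profiles.
    """
    groups = _validate_design(design)
    rng = _stage_rng(config.seed, "rna")
    n = len(gene_ids)
    samples = list(design)

    truth = SyntheticTruth()
    if group_means is not None:
        means = group_means.loc[list(gene_ids), [design[s] for s in samples]]
        mu_by_sample = means.to_numpy(dtype=float)
    else:
        for g in (bipolar_group, *photoreceptor_groups):
            if g not in groups:
                raise ValueError(f"group {g!r} absent from design")
        lo, hi = config.nb_mean_range
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        if planted_signs is None:
            signs = np.zeros(n, dtype=int)
            n_planted = int(round(config.planted_fraction * n))
            idx = rng.choice(n, size=n_planted, replace=False)
            signs[idx[: n_planted // 2]] = 1
            signs[idx[n_planted // 2 :]] = -1
        else:
            signs = np.array([planted_signs.get(g, 0) for g in gene_ids])
        half = config.planted_lfc / 2.0

        mean_cols: dict[str, np.ndarray] = {}
        for g in groups:
            if g == bipolar_group:
                mean_cols[g] = base * np.power(2.0, signs * half)
            elif g in photoreceptor_groups:
                mean_cols[g] = base * np.power(2.0, -signs * half)
            else:
                mean_cols[g] = base.copy()

        # contamination: photoreceptor-specific genes leak into bipolar
        null_idx = np.flatnonzero(signs == 0)
        if config.n_contaminant_genes > len(null_idx):
            raise ValueError("not enough null genes to plant contaminants")
        contam_idx = rng.choice(
            null_idx, size=config.n_contaminant_genes, replace=False
        )
        contaminants = set()
        for k, gi in enumerate(contam_idx):
            source = photoreceptor_groups[k % 2]
            other = photoreceptor_groups[(k + 1) % 2]
            high = float(np.exp(rng.uniform(np.log(500.0), np.log(2000.0))))
            mean_cols[source][gi] = high
            mean_cols[other][gi] = high / 64.0
            mean_cols[bipolar_group][gi] = config.contamination_fraction * high
            contaminants.add(gene_ids[gi])
        truth.planted_de = {
            g: int(s) for g, s in zip(gene_ids, signs) if s != 0
        }
        truth.contaminant_genes = contaminants
        mu_by_sample = np.column_stack(
            [mean_cols[design[s]] for s in samples]
        )

    depth = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(samples)))
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j in range(len(samples)):
        counts[:, j] = _nb_draw(
            rng, mu_by_sample[:, j] * depth[j], config.nb_dispersion
        )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=list(gene_ids), columns=samples),
        groups=pd.Series(dict(design)),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Single-cell matrix
# ---------------------------------------------------------------------------

def generate_single_cell(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    cluster_names: Sequence[str] = ON_CLUSTERS + OFF_CLUSTERS,
    cluster_means: pd.DataFrame | None = None,
) -> tuple[SingleCellMatrix, SyntheticTruth]:
    """Clustered single-cell counts drawn around per-cluster mean vectors.

    Cluster means default to a shared log-normal gene baseline modulated by
    (i) a population-level signature — two-fold-scale effects on a random
    10% of genes shared by all ON clusters, and likewise for OFF clusters —
    reflecting that bipolar populations have hundreds of population-level
    marker genes, and (ii) independent cluster-specific effects of the same
    scale on another 10% of genes.  Cells are Poisson draws around their
    cluster's means (the emulated upstream matrix holds normalized counts,
    so no per-cell depth variation is added).
    """
    if len(cluster_names) < 2:
        raise ValueError("at least two clusters are required")
    if config.n_cells_per_cluster < 1:
        raise ValueError("n_cells_per_cluster must be >= 1 (empty cluster)")
    rng = _stage_rng(config.seed, "single_cell")
    n = len(gene_ids)

    if cluster_means is None:
        baseline = rng.lognormal(mean=0.5, sigma=1.2, size=n)
        pop_effect: dict[str, np.ndarray] = {}
        for pop in (ON_CLUSTERS, OFF_CLUSTERS):
            effect = np.ones(n)
            marked = rng.random(n) < 0.10
            effect[marked] = np.power(2.0, rng.normal(0.0, 1.0, marked.sum()))
            for cl in pop:
                pop_effect[cl] = effect
        cols = {}
        for cl in cluster_names:
            effect = np.ones(n)
            marked = rng.random(n) < 0.10
            effect[marked] = np.power(2.0, rng.normal(0.0, 1.0, marked.sum()))
            cols[cl] = baseline * pop_effect.get(cl, 1.0) * effect
        cluster_means = pd.DataFrame(cols, index=list(gene_ids))
    else:
        cluster_means = cluster_means.loc[list(gene_ids), list(cluster_names)]

    cells, labels = [], []
    for cl in cluster_names:
        mu = cluster_means[cl].to_numpy()
        draws = rng.poisson(
            np.tile(mu, (config.n_cells_per_cluster, 1))
        )
        cells.append(draws.T)
        labels.extend(
            f"{cl}_cell{i:04d}" for i in range(config.n_cells_per_cluster)
        )
    counts = pd.DataFrame(
        np.hstack(cells), index=list(gene_ids), columns=labels
    )
    clusters = pd.Series(
        [c.rsplit("_cell", 1)[0] for c in labels], index=labels, name="cluster"
    )
    sc = SingleCellMatrix(counts=counts, clusters=clusters)
    return sc, SyntheticTruth(cluster_means=cluster_means)
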