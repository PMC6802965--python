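# Methods

This note documents the models and procedures implemented in `cisgrammar`,
the defaults of the synthetic-data generator, the numerical choices made
where the design was open, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Scope and model of the data

The package analyses the comparative regulatory genomics of two related
cell classes — photoreceptors and bipolar cells are the motivating pair —
from post-alignment products: peak intervals, peak sequences, count
matrices and cluster-labelled single-cell counts. Read alignment and peak
calling are out of scope; summits are taken as given (the synthetic
generator uses interval midpoints, since real summits come from a peak
caller).

A *cis*-regulatory grammar is summarised as the identity, frequency,
co-occurrence, spacing and orientation of transcription-factor binding
motifs within a cell class's open chromatin. The shipped motif set is a
small curated stand-in for a full motif database: one representative IUPAC
consensus per family that matters for the photoreceptor/bipolar comparison
(K50 homeodomain `TAATCC`, Q50 homeodomain `TAATTR` — one model covering
the `TAATTA`/`TAATTG` variants, E-box `CANNTG`, a simplified CTCF
consensus, a nuclear-receptor half site `RGGTCA`, MADS `CTAWWWWTAG`, plus
CRE and GC-box controls). Full position-weight-matrix databases and de
novo motif discovery are non-goals; a PWM path (log-odds matrix plus
threshold) exists for users who supply their own matrices.

## Motif statistics

**Scanning.** Both strands are scanned with exact IUPAC matching;
overlapping matches are all reported. A palindromic consensus (equal to
its own IUPAC reverse complement, e.g. `CANNTG`) would produce the same
site twice, once per strand, so those collapse to a single `+` occurrence;
non-palindromic motifs count each strand separately. Offsets are
summit-relative match starts.

**Presence, not counts.** All proportion statistics use peak-level
presence (>= 1 occurrence), i.e. the proportion of peaks *containing* a
motif; multiplicity feeds only the density and spacing profiles.

**Enrichment vs background.** The background for single-set enrichment is
dinucleotide-preserving shuffles of the peak sequences themselves
(Eulerian-path construction; two shuffles per peak by default), which
preserves composition exactly. A one-sided binomial test compares the
peak presence proportion with the background proportion; BH correction is
applied across motifs.

**Differential enrichment.** Two peak sets are compared per motif with the
classical two-sample test of equal proportions: the pooled z-test without
continuity correction, two-sided. The continuity-corrected variant is a
one-line change but is not the default, keeping the plain-z contract.

**Co-occurrence.** For a motif pair, observed = peaks containing both;
expected = n1·n2/N under independence; the score is
log2((observed+1)/(expected+1)). Differential co-occurrence between peak
sets uses Fisher's exact test on the 2x2 pair-presence table, BH across
pairs. BH is applied within each analysis (all motifs, or all pairs), not
globally.

**Spacing.** Secondary-motif positions are histogrammed relative to each
anchor occurrence, with offsets negated for minus-strand anchors and the
secondary strand recorded relative to the anchor ("same"/"opposite");
self-pairs (same motif, position and strand) are excluded. Densities are
per bp per 1000 anchors.

**Density units.** Density profiles report motifs per base pair per 1000
peaks: count / (bin width x n_peaks/1000). The conservation identity
sum(density x bin x n_peaks/1000) = total in-window occurrences holds by
construction.

**In-silico mutagenesis.** Homeodomain sites are edited in place:
`TAAT -> TGGT` inactivates a site; the Q50 conversion rewrites the 6-mer
at the site to `TAATTA`. Sequence length is always preserved and a
non-`TAAT` site is an error.

## Differential counts

Normalization is median-of-ratios: factor_j = median over features
(nonzero in every sample) of count_ij / geometric mean_i. Dispersion is
per-feature method-of-moments on normalized counts, alpha =
(s^2 - mean)/mean^2 pooled across groups by degrees of freedom and floored
at 1e-8; there is deliberately no empirical-Bayes shrinkage toward a
fitted trend, so feature-level results will not numerically match
shrinkage-based packages on real data — dataset-level counts from real
studies are therefore not reproduction targets of this package.

The Wald test works on log2 fold-changes of normalized group means with a
0.5 pseudocount (keeping fold-changes finite for zero groups). The
standard error comes from the NB variance mu + alpha·mu^2 of each group
mean by the delta method. p-values use a t reference with
df = n_samples − n_groups rather than the normal: with per-feature moment
dispersion at typical replicate numbers (4 vs 4) the statistic is
Welch-like with few denominator degrees of freedom, and the normal
reference is visibly anticonservative; the t reference makes the null
rejection rate match the nominal level and the null p-values uniform
(both properties are asserted in the test suite). A feature is "called"
when |log2FC| >= 1 and BH FDR < 0.05, applied as a post-hoc filter; a
`shifted_null` flag instead folds the fold-change threshold into the Wald
null (one-sided test of |log2FC| <= threshold) for users who prefer
threshold-aware testing.

Sample structure is summarised by Pearson correlation of
log2(normalized+1) profiles and average-linkage hierarchical clustering on
1 − r; scipy's deterministic linkage and leaf order make repeated runs
identical. A constant sample vector is an error naming the sample.

## Contamination filter

Sorted bipolar populations carry low-level photoreceptor contamination, so
photoreceptor-specific genes can appear bipolar-enriched when bipolar
cells are compared against the *other* photoreceptor type. From each
bipolar-enriched called list, the filter removes genes that are strictly
> 16-fold specific to the alternate photoreceptor (vs the comparison
photoreceptor) and >= 4-fold higher in that photoreceptor than in the
bipolar population ("at least four-fold" read as inclusive, "> 16 fold" as
strict). For a comparison between two bipolar populations, a gene
enriched in one population is removed when both photoreceptor types exceed
it > 16-fold. Ratios use normalized means with the 0.5 pseudocount. The
filter runs after the differential test, on its output tables; removed
genes are reported with their triggering ratios, never silently dropped.
Statistical significance of the specificity ratio is not additionally
required — the thresholds are fold-change rules by design.

## Integration and pseudo-bulk

Each differentially accessible peak is paired with its nearest-TSS gene
(summit-to-TSS distance; ties broken toward the lexicographically smaller
gene id for cross-platform reproducibility; peaks on TSS-free chromosomes
are flagged, not dropped). The accessibility x expression plane is
classified with four-fold (|log2FC| >= 2, inclusive) and FDR < 0.05 cuts
in *both* dimensions: concordant toward one class, discordant when both
dimensions pass in opposite directions, shared-or-modest otherwise. Peaks
whose assigned gene lacks an expression record are excluded and reported
rather than imputed. Promoter classification is summit-based (summit
within 1000 bp upstream to 100 bp downstream of a TSS, strand-oriented,
bounds inclusive); overlap anywhere in the peak body is a defensible
alternative, but the summit rule is deterministic under peak-width
changes.

Pseudo-bulk vectors are cell-count-weighted averages of cluster means —
exactly the plain mean over all member cells — for populations defined as
cluster sets (defaults: the ON bipolar clusters RBC, BC5A, BC5C, BC5D,
BC6, BC7, BC8/BC9; the OFF clusters BC1A, BC1B, BC2, BC3A, BC3B, BC4; and
their union as pan-bipolar). Rescaling to bulk uses a single global
factor matching totals over the shared gene universe, which leaves
correlations unchanged. Bulk/pseudo-bulk correlations are Pearson on
log2(x+1); cells are not re-normalized before averaging (the input matrix
is already normalized upstream).

## The synthetic-data generator

Every generator is a pure function of (config, seed); per-stage streams
are derived deterministically from the run seed, so regenerating any stage
is bit-identical. Defaults define the reference study conditions:

* **Genome and peaks.** One 1 Mb chromosome, uniform base composition;
  200 bp peaks laid out non-overlapping on a 2x-width stride, 500 peaks
  per category (photoreceptor-specific, bipolar-specific, shared,
  control tissue), summit = midpoint. Motif instances (Poisson counts per
  peak) are written into the sequence at uniform positions within the
  central 80% of each peak — avoiding edge truncation so density profiles
  stay interpretable — without overlapping one another, on random strands;
  the truth table records every planting. Planted densities per peak:
  K50 2.0 in photoreceptor/bipolar/shared; Q50 1.5 in
  photoreceptor-specific peaks only; E-box 1.5 in bipolar-specific, 0.3 in
  photoreceptor-specific, 0.5 in shared; CTCF 1.5 in shared and control
  peaks — the qualitative grammar of the motivating comparison
  (shared K50 machinery, Q50 partitioned to photoreceptors, E-boxes toward
  bipolar cells, CTCF in ubiquitously open regions).
* **Counts.** Negative-binomial with Var = mu + alpha·mu^2, alpha = 0.05,
  base means log-uniform in [50, 1000], four replicates per group, and
  mild per-sample depth factors (log-uniform in [0.7, 1.4]) so
  normalization is actually exercised. Planted differential features get
  an expected |log2FC| of `planted_lfc` (default 3), split symmetrically
  around the base mean; null features share one mean across groups.
* **Contamination.** Contaminant genes are strongly specific to one
  photoreceptor type (64-fold over the other) with zero intrinsic bipolar
  expression; bipolar samples receive contamination_fraction (default 5%)
  times the source-photoreceptor mean, an additive mean shift rather than
  mixture resampling — the simplest model of low-level carry-over.
* **Single cell.** Cluster means = log-normal gene baseline x a
  population-level signature (two-fold-scale effects on 10% of genes
  shared by all ON clusters, likewise OFF — real bipolar populations have
  hundreds of population-level markers) x independent cluster effects of
  the same form; cells are Poisson draws (the emulated input is a
  normalized matrix, so no per-cell depth is added); 200 cells per
  cluster.

What the generator does **not** emulate: read-level data (FASTQ),
fragment-length and Tn5 insertion bias, realistic genome annotation,
correlated motif placement, GC-dependent coverage, and mean-dependent
dispersion trends. Passing benchmarks on this data therefore demonstrates
the correctness and calibration of the statistics under the stated model,
not pipeline performance on raw sequencing data.

## Reference experiments and problem sizes

`cisgrammar.workflows` packages the benchmark experiments used by the test
suite and `scripts/acceptance.py`. Chosen problem sizes: independence
null — 2000 peaks x 32 independently planted motifs (496 pairs, presence
probability ~0.63); grammar recovery — 400 peaks per class; test
calibration — 2000 null features and 2000 features with 20% planted at
|log2FC| = 2, 4 vs 4 replicates, means in [200, 1000]; contamination —
2500 genes with 60 planted contaminants at 5%; quadrant pipeline — 300
peaks per category with |log2FC| = 3 planted concordantly; pseudo-bulk —
100 seeded runs of 1500 genes x 13 clusters x 200 cells with matched bulk
at 100x depth and 2 replicates. Contamination-filter recovery counts a
contaminant as handled when no final kept list reports it as a called
bipolar-enriched gene — genes the differential stage never lists cannot
contaminate downstream results, whether or not the fold filter also fires.

## Numerical choices and degenerate inputs

* Coordinates are BED convention (0-based, half-open); overlap means >= 1
  shared base; chromosome names are compared as raw strings and distinct
  chromosomes never overlap.
* Dispersion floor 1e-8; fold-change pseudocount 0.5; BH within analysis.
* Equidistant nearest-TSS ties: lexicographically smaller gene id.
* Palindrome collapse prevents double counting; the degenerate Q50
  consensus is one model (`TAATTR`), not two.
* Degenerate inputs raise informative errors rather than propagating NaN:
  empty peak sets for enrichment/overlap, zero-length genomes, single
  replicates (dispersion unidentifiable), constant samples in clustering,
  empty single-cell clusters or populations, all-zero pseudo-bulk vectors,
  missing cross-comparison tables in the contamination filter (named).

## Known limitations

* No dispersion shrinkage or GLM designs beyond two-group contrasts;
  batch covariates are out of scope.
* Consensus matching has no affinity model unless a PWM is supplied;
  match-score thresholds for the shipped set are not calibrated to any
  external database's cutoffs.
* The contamination filter is rule-based; deconvolution-based estimation
  is out of scope.
* Peak-gene linking is nearest-TSS only; no 3-D contact information.
* The single-cell generator plants cluster labels rather than clustering
  cells; clustering quality is not this package's concern.
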