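# cisgrammar

Comparative analysis of the *cis*-regulatory grammars of related cell
classes from open-chromatin (ATAC-seq / DNase-seq) peak sets and bulk /
single-cell transcriptomes — built around the photoreceptor vs bipolar-cell
comparison in the mouse retina, and exercised end to end on synthetic data
with planted ground truth.

## Who this is for

Regulatory genomicists comparing two related cell classes who have
post-alignment products in hand — peak intervals (BED), peak sequences
(FASTA), per-peak / per-gene count matrices (TSV), TSS annotations, and a
clustered single-cell matrix — and want a tested, scriptable pipeline for:

* **Motif grammar statistics.** Scan IUPAC consensus motifs on both
  strands (a curated set ships with the package: K50 homeodomain `TAATCC`,
  Q50 homeodomain `TAATTR`, E-box `CANNTG`, CTCF, nuclear-receptor and
  MADS-box sites); test per-motif enrichment against a
  dinucleotide-shuffled background (one-sided binomial); compare the
  proportion of peaks containing each motif between two peak sets with a
  two-proportion z-test; profile summit-anchored motif density (motifs per
  bp per 1000 peaks); score motif-pair co-occurrence against the
  independence expectation, `log2((obs + 1) / (exp + 1))` with
  `exp = n1 * n2 / N`, and compare pair frequencies between peak sets with
  Fisher's exact test; plot stranded spacing profiles of a secondary motif
  around anchor motifs; and run in-silico motif edits (`TAAT -> TGGT`
  knockout, K50 -> Q50 `TAATTA` conversion).
* **Interval algebra.** Peak-set unions, promoter vs enhancer calls
  (summit within 1000 bp upstream to 100 bp downstream of a TSS,
  strand-aware), nearest-TSS gene assignment, overlap fractions, and
  tissue-specificity filtering against control tissues.
* **Differential counts.** Median-of-ratios normalization, per-feature
  method-of-moments dispersion for the negative-binomial model
  `Var = mu + alpha * mu^2`, a Wald test on `log2FC` of normalized group
  means with Benjamini–Hochberg correction (called at `|log2FC| >= 1` and
  `FDR < 0.05`), and sample correlation / average-linkage clustering.
* **Contamination filtering.** Rule-based removal of photoreceptor
  carry-over genes from bipolar differential-expression lists
  (> 16-fold specific to the alternate photoreceptor type and >= 4-fold
  above the bipolar population).
* **Accessibility–expression integration.** Pair each differential peak
  with its nearest-TSS gene and classify the accessibility x expression
  plane into concordant / discordant / shared-or-modest quadrants
  (four-fold and FDR < 0.05 in both dimensions).
* **Pseudo-bulk comparison.** Aggregate clustered single-cell counts into
  population profiles (cell-count-weighted averages), rescale to bulk
  totals, and correlate against bulk RNA-seq on log2(x + 1) values.

The `cisgrammar.synthetic` module generates every one of those inputs with
planted ground truth — genomes with motif instances written in at
class-specific densities, negative-binomial count matrices with planted
differential features and planted contamination, and clustered single-cell
matrices — so each stage is testable without any external download.

## Worked example

Recover the planted grammar — Q50 sites only in photoreceptor-specific
peaks, E-boxes enriched in bipolar-specific peaks, K50 sites in both:

```python
import cisgrammar as cg

cfg = cg.SimulationConfig(n_peaks_per_class=400, seed=1)
genome = cg.generate_genome(cfg)
peaks, truth = cg.generate_peak_sets(cfg, genome)

presence = {}
for cell_class in ("photoreceptor", "bipolar"):
    seqs = cg.peak_sequences(genome, peaks[cell_class])
    occ = cg.scan_motif_set(seqs, cg.load_motifs())
    presence[cell_class] = cg.motif_presence([s.peak_id for s in seqs], occ)

res = cg.differential_motif_enrichment(
    presence["photoreceptor"], presence["bipolar"]
)
cols = ["motif", "proportion_a", "proportion_b", "statistic", "fdr"]
print(res[cols].round(3).to_string(index=False))
```

prints

```
      motif  proportion_a  proportion_b  statistic   fdr
        CRE         0.000         0.010     -2.005 0.105
       Ebox         0.600         0.898     -9.700 0.000
     GC_box         0.078         0.060      0.978 0.459
     K50_HD         0.872         0.880     -0.322 0.872
       MADS         0.010         0.002      1.346 0.312
NR_halfsite         0.150         0.152     -0.099 0.921
     Q50_HD         0.800         0.142     18.628 0.000
```

`proportion_a` / `proportion_b` are the fractions of photoreceptor and
bipolar peaks containing each motif. Q50 sites are present in 80% of
photoreceptor-specific peaks but only 14% of bipolar-specific peaks
(z = 18.6, FDR << 0.05: significant toward photoreceptors); E-boxes run
the other way (z = -9.7); K50 sites are abundant in both classes and not
differential — the planted grammar, recovered.

The same steps are available from the shell: `cisgrammar simulate`,
`union`, `classify`, `assign-tss`, `filter-specific`, `scan`, `enrich`,
`diff-enrich`, `density`, `cooccur`, `spacing`, `mutate`, `diff`,
`cluster`, `pseudobulk` (see `cisgrammar --help`).

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generator and its defaults, numerical choices, and known limitations.
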