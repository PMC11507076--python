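# Methods

## The analysis model

`concordome` compares omic layers of one sample at the level of *gene
detection sets* and, secondarily, at the level of abundance magnitudes.
Everything is computed against a fixed universe of reviewed
protein-coding genes (default size 20,423), which makes percentages from
different layers and samples directly comparable. The pipeline makes
three modelling commitments:

1. **Gene-centric pooling.** Isoform RPKM values are summed per gene.
   Summation conserves read mass — a gene's RPKM is the total over its
   transcripts, matching what RSEM reports at the gene level. Pooling by
   the dominant isoform (`method="max"`) is available but not the
   default, since it understates genes with many moderately expressed
   isoforms.
2. **Detection by strict thresholding.** A gene is detected at cutoff
   *t* iff its abundance is strictly greater than *t*. At *t* = 0 this
   excludes exact zeros, which is what makes detected counts smaller
   than the universe. RPKM layers share one cutoff ladder
   (0, 0.1, 1, 5, 10); proteome tables are always thresholded at LFQ
   intensity > 0 because LFQ is not on the RPKM scale.
3. **Within-sample comparison only.** RPKM is comparable across methods
   within one sample; no between-sample normalization, TPM conversion or
   batch correction is attempted.

### Tanimoto similarity and its bands

Set concordance is the Tanimoto (Jaccard) ratio
T(a, b) = |a∩b| / (|a| + |b| − |a∩b|), swept over the cutoff ladder.
Interpretation bands follow the conventional scale: T ≥ 0.7 "identical",
0.55 ≤ T < 0.7 "weakly similar", T < 0.55 "significantly different".
Each stated range is treated as closed on its upper edge (0.7 is
"identical", 0.55 is "weakly similar"); the boundary assignment is a
convention — continuous data essentially never lands on it exactly. Two
empty sets are defined to be identical (T = 1) and the profile row is
flagged, so degenerate high cutoffs fail loudly rather than crash.

### Correlation and the permutation test

Quantitative agreement is computed over genes detected in **both**
tables (log10 is applied after thresholding, so zeros never reach the
log). Both Spearman ρ (mid-ranks for ties) and Pearson *r* on log10
values are reported, with R² = r²; which of the two a reader wants
depends on whether they care about monotone or linear agreement, so
neither is hidden. The p-value is a two-sided permutation test on the
Spearman statistic, shuffling one table's values with a seeded
generator and using the add-one estimate
p = (1 + #{|ρ\*| ≥ |ρ|}) / (1 + N); the add-one keeps p > 0 and makes
the null distribution of p super-uniform. For n ≤ 8 all n! orderings
are enumerated instead and the exact tail proportion is returned.
Permuted statistics are compared against |ρ| − 10⁻¹², so permutations
numerically tied with the observed value count as at least as extreme.

### Copy classes and the portrait

Positive abundances are binned into (0.1, 1], (1, 10], (10, 100],
(100, 1000], (1000, 10000]. The bins are half-open on the left and
closed on the right so that they tile the positive axis and their edges
coincide with the cutoff ladder; values at an edge (rare in continuous
RPKM data) go to the lower bin. Genes with 0 < RPKM ≤ 0.1 form an
explicit below-range bin rather than disappearing; values above 10,000
are counted in the top bin and reported separately.

The multiomic portrait flags every universe gene as
(transcribed, translated, protein detected) and tabulates the eight
resulting categories; the counts partition the universe exactly and the
percentages use the same decimal rounding as all coverages. The
translatome layer defaults to RNC-seq; Ribo-seq or the per-gene maximum
of both can be selected. All eight categories are always reported — the
three biologically prominent ones (all levels, transcribed-and-
translated-without-protein, genome-only) are not privileged in the
data structure, only in discussion.

### Rounding

Coverage percentages are rounded half-away-from-zero to one decimal
using exact decimal arithmetic. This matters: 16,655/20,423 is
81.5511...%, and binary floating point can round such values the wrong
way at the last printed digit.

## The synthetic generator

The generator emulates the *shape* of a real multiomic experiment at
the level the pipeline consumes — gene-by-abundance tables — not reads,
footprints or spectra.

* **Detection sets are constructed, not sampled by coin flips.** For
  target coverages and Jaccard J, set sizes nA = round(cov·N),
  nB and the intersection k = round(J(nA+nB)/(1+J)) are hit exactly by
  drawing k shared genes, then the uniques, without replacement.
  Infeasible targets (k outside [max(0, nA+nB−N), min(nA, nB)]) raise
  with the feasible Jaccard range. Exact construction is what lets
  end-to-end tests assert set-level recovery *exactly* rather than
  within sampling noise.
* **Magnitudes** are log-normal: log10 RPKM = μ + σ(√c·t + √(1−c)·e)
  with a shared per-gene factor *t*, so any two layers with loadings
  c₁, c₂ correlate at √(c₁c₂) on the log10 scale. The two translatome
  methods share c = `log10_r`, giving them exactly that correlation;
  the RNA loading is solved from the requested RNA–translatome
  correlation.
* **Proteome detection** is Bernoulli with probability
  logistic(β₀ + β₁·z̄), where z̄ is the gene's mean log10 RPKM over the
  layers that detected it — encoding the observed trend that highly
  expressed genes are more often seen by LC-MS/MS. Genes expressed in
  no sequencing layer cannot yield protein. LFQ intensities for
  detected proteins are an independent log-normal (they carry no
  cross-layer correlation structure; nothing downstream uses LFQ
  magnitudes beyond thresholding).
* **Reproducibility.** One seed sequence per bundle, spawned into five
  independent sub-streams (sets, magnitudes, RNA set, proteome, LFQ),
  so adding or regenerating one table never perturbs the others.
  Identical configs serialize byte-identically.

### Default study conditions

Defaults reproduce the MCF-7-like regime the analysis was designed
around, on the full 20,423-gene universe:

| parameter | default | rationale |
|---|---|---|
| `coverage_a` (RNC-seq) | 16,351/20,423 | intersection 15,676 + 675 uniques |
| `coverage_b` (Ribo-seq) | 16,364/20,423 | intersection 15,676 + 688 uniques |
| `target_jaccard` | 15,676/17,039 ≈ 0.92 | translatome Venn at RPKM > 0 |
| `coverage_rna` | 16,655/20,423 ≈ 81.6% | transcriptome detection |
| `log10_mu`, `log10_sigma` | 0.5, 0.8 | mode of detected genes in (1, 10], tens of genes above RPKM 500 |
| `log10_r` | 0.98 | log10 correlation between translatome methods (R² ≈ 0.96) |
| `rna_translatome_r` | 0.90 | high but imperfect transcriptome–translatome agreement |
| `proteome_logistic` | (−1.0, 1.2) | ≈40% detection of expressed genes, rising with expression; proteome coverage lands in the low-to-mid 30s percent |
| `lfq_log10_mu/sigma` | 3.2, 0.6 | LFQ intensities in the 10²–10⁴ range typical of label-free runs |

The published MCF-7 summary counts are mutually inconsistent at the
margin: the dataset-level table reports 16,622 (RNC) and 16,641 (Ribo)
detected genes, while the Venn's union and unique counts imply 16,351
and 16,364, and the stated Tanimoto at RPKM > 0 is 0.89 where the Venn
counts give 15,676/17,039 ≈ 0.92. The generator defaults follow the
internally consistent Venn triple; the statistics are always computed
from whatever sets they are given, with no attempt to reconcile the
printed figures.

### What the generator does not emulate

No read-level noise, no isoform structure (the bundle is already
gene-level; isoform pooling is tested on separate fixtures), no
zero-inflation beyond undetected-gene zeros, no heavy-tailed RPKM
departures from log-normality, no shared-peptide ambiguity in the
proteome, and no between-method bias in magnitudes (both translatome
layers share μ and σ). Passing tests therefore demonstrate the
*statistics and their wiring* are correct under the stated structure;
they do not validate robustness to real-data artefacts such as
mapping bias or proteome dynamic-range compression.

## Numerical and design choices

* Detection uses strict `>` everywhere; a value exactly equal to the
  cutoff is not detected.
* Percent rounding: decimal, half-away-from-zero, one decimal; the
  complement identity pct(n) + pct(N−n) = 100 holds to ±0.1.
* Venn regions are keyed by membership bit-strings in set order
  ("11" = both of two sets) and always sum to the union size.
* The correlation refuses fewer than 3 shared genes or constant
  columns rather than returning NaN.
* Report serialization is deterministic: similarities print with 4
  decimals, percentages with 1, thresholds in compact `%g` form; JSON
  is the machine-readable surface, TSV the human one.
* Problem sizes in the test suite are scaled to what the statistics
  need: exact-recovery checks run on universes of a few hundred to a
  few thousand genes, correlation recovery on the full default bundle
  (~15,700 shared genes), and the null-calibration check on 500
  simulated null pairs of 16 genes with 199 permutations each — enough
  for the 3·SE bound to be meaningful.

## Limitations

* Gene identity is by symbol match after upper-casing; no alias or
  cross-reference resolution is attempted, so identifier mismatches
  between quantifier and universe silently reduce coverage (dropped
  counts are logged and reported).
* The Tanimoto bands are descriptive conventions, not inferential
  statements; no null distribution is attached to a band assignment.
* The permutation test assumes exchangeability of one table's values
  under the null; it tests association, not agreement in magnitude.
* RPKM-based detection inherits RPKM's known depth sensitivity; the
  cutoff ladder exists precisely to expose how conclusions move with
  the threshold.
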