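# concordome

Gene-centric concordance analysis across the transcriptome, translatome
and proteome of one biological sample.

Translation can be profiled two fundamentally different ways: **Ribo-seq**
sequences short ribosome-protected mRNA fragments, while **RNC-seq**
sequences the full-length mRNAs bound in ribosome–nascent chain
complexes. Both end in a gene-level RPKM table, and a natural question
for anyone running either assay is how concordant the two views of the
translatome are — and how the translatome sits between the transcriptome
(RNA-seq) and the proteome (LC-MS/MS LFQ intensities) of the same
sample. `concordome` is for bench and computational groups who already
have quantification tables (RSEM-style TSVs) and want the downstream
set-level and quantitative comparison done reproducibly.

## What it computes

All analysis is *gene-centric*: isoform RPKM values are pooled (summed)
to one value per protein-coding gene, tables are restricted to a fixed
universe of reviewed protein-coding genes (PCGs; the denominator for
every percentage), and a gene counts as *detected* at cutoff *t* when
its abundance is strictly greater than *t*.

* **Detection coverage** per omic layer over an RPKM cutoff ladder
  (0, 0.1, 1, 5, 10), reported as percentages of the PCG universe.
* **Tanimoto similarity** between two detection sets *a*, *b*:

  `T(a, b) = |a ∩ b| / (|a| + |b| − |a ∩ b|)`

  swept across the cutoff ladder, with interpretation bands
  T ≥ 0.7 "identical", 0.55 ≤ T < 0.7 "weakly similar",
  T < 0.55 "significantly different".
* **Venn partitions** of 2–3 detection sets with exact region counts.
* **Quantitative concordance**: Spearman ρ and Pearson *r* of
  log10 RPKM over genes detected by *both* methods, with a seeded
  permutation p-value (exact enumeration for n ≤ 8).
* **Copy-class histograms**: (0.1, 1], (1, 10], (10, 100],
  (100, 1000], (1000, 10000] RPKM bins plus an explicit below-range bin.
* **Multiomic portrait**: each PCG is flagged
  (transcribed, translated, protein detected), giving eight categories
  that partition the universe, with counts and percentages.
* **Synthetic bundles**: a generator that emulates the study conditions
  (configurable coverages, an *exact* Jaccard overlap between the two
  translatome methods, log-normal RPKM correlated on the log10 scale,
  proteome detection probability rising logistically with expression),
  so the whole pipeline can be exercised and validated without any
  sequencing data.

## Worked example

```python
from concordome import (SyntheticConfig, generate_bundle, detected_set,
                        tanimoto_profile, venn_counts, log_rpkm_correlation,
                        coverage_percent)

bundle = generate_bundle(SyntheticConfig(seed=1))
n = bundle.universe.size
for table in (bundle.rna, bundle.rnc, bundle.ribo):
    k = len(detected_set(table, 0.0))
    print(f"{table.layer_label:9s} {k:6d} genes ({coverage_percent(k, n)}% of {n})")

profile = tanimoto_profile(bundle.rnc, bundle.ribo)
for row in profile.rows:
    print(f"RPKM > {row.threshold:<4g} T = {row.similarity:.4f}  ({row.band})")

venn = venn_counts([detected_set(bundle.rnc, 0.0), detected_set(bundle.ribo, 0.0)])
print(f"venn: both = {venn.region_counts['11']}, union = {venn.union_total}")

corr = log_rpkm_correlation(bundle.rnc, bundle.ribo, 0.0, n_permutations=999, seed=1)
print(f"r = {corr.pearson_r_log10:.4f}, R^2 = {corr.r_squared:.4f}, "
      f"rho = {corr.spearman_rho:.4f}, p = {corr.p_value:.4g} (n = {corr.n_shared})")
```

prints

```
RNA-seq    16655 genes (81.6% of 20423)
RNC-seq    16351 genes (80.1% of 20423)
Ribo-seq   16364 genes (80.1% of 20423)
RPKM > 0    T = 0.9200  (identical)
RPKM > 0.1  T = 0.9099  (identical)
RPKM > 1    T = 0.8578  (identical)
RPKM > 5    T = 0.7937  (identical)
RPKM > 10   T = 0.7541  (identical)
venn: both = 15676, union = 17039
r = 0.9802, R^2 = 0.9608, rho = 0.9780, p = 0.001 (n = 15676)
```

Reading: the two translatome methods each see ~80% of the 20,423-gene
universe; 15,676 genes are detected by both (92% of the 17,039-gene
union, T = 0.92, "identical" band); their log10 RPKM values agree with
R² ≈ 0.96 and the permutation test leaves no doubt the association is
real. The Tanimoto coefficient decays as the cutoff rises because the
methods disagree more about marginally expressed genes.

The same pipeline runs from the shell over TSV inputs:

```
concordome simulate --seed 1 -o sim/
concordome concord  --table-a sim/rnc.tsv --table-b sim/ribo.tsv \
                    --universe sim/universe.txt -o concord/
concordome portrait --rna sim/rna.tsv --rnc sim/rnc.tsv --ribo sim/ribo.tsv \
                    --proteome sim/proteome.tsv --universe sim/universe.txt -o portrait/
```

Every report is written as TSV and JSON; identical inputs and seed give
byte-identical files.

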