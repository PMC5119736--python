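# dhsenrich

Quantifies excess overlap between GWAS susceptibility loci and cell- or
tissue-specific DNase I hypersensitive sites (DHSs), using a
covariate-matched null-SNP resampling model.  Open chromatin is highly
cell-type specific, so a disease's lead variants clustering near DHSs that
are active in one tissue is evidence that the tissue participates in the
disease mechanism.  The package is aimed at statistical geneticists and
regulatory genomicists who want a linkage-disequilibrium-insensitive,
permutation-based enrichment test, plus a synthetic-data generator that
plants a known enrichment so every stage of the pipeline can be validated
without external downloads.

## The model

For a GWAS with lead SNPs $s_1, \dots, s_m$, each SNP defines a
susceptibility locus: a window of width $w$ (default 500 kb) centered on
the SNP, clipped to its chromosome; overlapping windows of neighboring
SNPs merge into a single locus, so loci are pairwise disjoint.  For a DHS
track $D$ the observed statistic is

$$X_{\text{obs}} = \sum_{\ell} \#\{\,d \in D : d \cap \ell \neq \emptyset\,\}$$

counting every peak that shares at least one base with a locus (half-open
intervals; abutment is not overlap).  The null distribution comes from
$N = 50{,}000$ matched sets of random loci: for each observed locus, a
background SNP is drawn uniformly from the pool of SNPs matching the lead
SNP on

* minor allele frequency, $|\Delta\text{MAF}| \le 0.05$;
* signed distance to the nearest TSS, in the same of 12 location bins
  with boundaries ±200 kb, ±100 kb, ±25 kb, ±10 kb, ±5 kb and 0;
* local gene density: TSS count within $\pm w/2$, in the same of three
  categories (0–9, 10–24, ≥ 25),

and a null window of the observed locus's span is centered on it.  With
null counts $X_1, \dots, X_N$,

$$\text{FE} = \frac{X_{\text{obs}}}{\bar X_{\text{null}}}, \qquad
\hat p = \max\!\left(\frac{k}{N}, \frac{1}{N}\right),\quad
k = \#\{j : X_j \ge X_{\text{obs}}\},$$

a one-sided empirical p-value with floor $1/N = 2\times10^{-5}$ at the
default $N$.  Replicate DHS assays of one tissue are aggregated as the
average fold enrichment AFE ± SD, with the minimum replicate p reported
alongside all per-replicate values.  Studies are stratified by their best
p across all DHS samples into green (≤ 1e-4), orange (≤ 1e-2) and red
(> 1e-2) groups, whose covariates can be compared with rank-sum tests.

## Worked example

`examples/01_single_study_enrichment.py` simulates a 20-locus GWAS and a
tissue whose peak density inside the trait loci is 1.5× background (three
replicates), plus an unenriched control tissue, then runs the matched-null
test with 5,000 null sets:

```
study SIM001: 20 susceptibility loci (50 kb windows)
sample                tissue              obs  null_mean     FE         p
target_tissue_rep1    target_tissue       150      95.44  1.572    0.0002
target_tissue_rep2    target_tissue       152      95.92  1.585    0.0002
target_tissue_rep3    target_tissue       151      95.96  1.574    0.0002
background_1_rep1     background_1         91      94.94  0.959      0.68
background_1_rep2     background_1         95      94.87  1.001      0.51
background_1_rep3     background_1         93      95.43  0.975      0.62

replicate-aggregated tissue summaries (AFE = mean replicate FE):
  background_1       AFE = 0.978 +/- 0.022  (min replicate p = 0.51, n = 3)
  target_tissue      AFE = 1.577 +/- 0.007  (min replicate p = 0.0002, n = 3)
```

The planted tissue recovers the planted factor (FE ≈ 1.57 vs f = 1.5,
within Monte-Carlo noise) at the p floor for 5,000 sets, while the control
sits at FE ≈ 1 with non-significant p — the calibrated null.  The other
examples dissect the matching covariates of a single tag SNP
(`02_null_matching_demo.py`) and stratify twelve simulated GWAS into
green/orange/red groups (`03_gwas_groups.py`).

## Command line

The same pipeline is exposed as a thin CLI for file-based runs:

```bash
dhsenrich simulate --out-dir fixture --seed 7 --enrichment-factor 1.5
dhsenrich enrich --fixture-dir fixture --n-sets 5000 --window-size 50000
dhsenrich report --out-dir fixture/results
```

`enrich` writes three TSVs (per-pair detail, tissue summaries with
AFE ± SD, study summaries with group assignments), each headed by a
comment recording the seed and a hash of the scientific parameters; reruns
with the same config are byte-identical.

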