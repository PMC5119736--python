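# Methods

## The enrichment model

The statistic tests whether the susceptibility loci of one GWAS contain
more DNase I hypersensitive sites from one sample than expected for
random genomic windows with comparable properties.  Its assumptions:

* **Locus definition.** Each lead SNP stands for an association peak; a
  fixed window of width `w` (default 500,000 bp) centered on the SNP is
  treated as the susceptibility region.  The window is deliberately wide
  enough to cover local linkage disequilibrium and most distal
  promoter–enhancer contacts, which makes the test insensitive to the LD
  structure around any particular lead SNP.  Windows of neighboring SNPs
  that overlap (strictly — half-open windows that merely touch stay
  separate) merge transitively into one locus keeping the union extent,
  so no peak can be counted twice within a study.  Windows are clipped at
  chromosome ends rather than shifted; shifting would distort the
  TSS-distance covariate of edge loci.
* **Overlap rule.** A peak overlaps a locus when they share at least one
  base.  Counts are per locus: a peak spanning two disjoint loci
  contributes to both, and observed and null windows are treated
  identically, so the convention cancels in the fold ratio.
* **Null model.** Lead SNPs are not random positions: arrays
  preferentially assay common variants, and association peaks cluster
  near genes.  The null therefore resamples, for each observed locus, a
  background SNP matched to the locus's representative SNP on folded
  MAF (absolute half-width 0.05 — an absolute window, since a relative
  ±5% collapses the candidate pool at low MAF), on signed nearest-TSS
  distance bin, and on local gene density category, and centers a window
  of the observed locus's span on it.  One matched SNP per merged locus
  is drawn (matching operates on SNPs, not loci; copying the merged span
  keeps overlap opportunity comparable), uniformly with replacement
  across and within sets.  Null windows are not merged with one another:
  merging them would shrink null overlap opportunity non-uniformly, and
  collisions are rare and unbiased.  An empty candidate set is a hard
  error — matching is never silently relaxed.
* **Statistics.** Fold enrichment is the observed count over the null
  mean; the p-value is one-sided (excess overlap only),
  `max(k, 1)/N` with `k` the number of null sets reaching the observed
  count.  The estimator has a floor of `1/N`; at the default
  `N = 50,000` the smallest reportable p is exactly 2×10⁻⁵.  The null SD
  uses the population convention (the vector is the entire Monte-Carlo
  population); the SD across biological replicates uses the sample
  convention (replicates are a sample of possible assays).  Ties count
  against significance, which makes the test conservative on discrete
  counts.

## Matching covariates

* **Signed TSS distance.**  Distance to the nearest TSS on the same
  chromosome, negative when the SNP is 5′ of the gene (upstream with
  respect to strand), positive downstream, 0 at the TSS.  Distance ties
  between two TSS break toward the smaller coordinate for determinism.
  Chromosomes without any annotated TSS are rejected at
  covariate-computation time — the covariate is undefined there.
  The 11 boundaries (±200 kb, ±100 kb, ±25 kb, ±10 kb, ±5 kb, 0) close
  into 12 right-closed bins with two unbounded tails; a distance of 0
  falls in (−5 kb, 0].  An `absolute_distance` switch bins |distance|
  instead, for users preferring an unsigned convention.
* **Gene density.**  TSS count within ±w/2 of the SNP, categorised
  0–9 / 10–24 / ≥ 25.
* **Replicate aggregation.**  AFE is the arithmetic mean of replicate
  fold enrichments with sample SD; the summary p per tissue is the
  minimum replicate p.  The minimum is a deliberate, optimistic
  convention — it is flagged as such and every per-replicate value is
  retained in the output, so users can substitute any combination rule.
* **Group comparisons.**  Green/orange/red strata (best p ≤ 1e-4,
  ≤ 1e-2, > 1e-2; boundaries inclusive on the significant side) are
  compared metric-by-metric with a two-sided unpaired Mann–Whitney
  rank-sum test.  A paired signed-rank statistic is not applicable to
  independent groups of unequal size.  No multiple-testing correction is
  applied to the headline significant-pair count; a Benjamini–Hochberg
  column is emitted alongside for users who want one.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the package's study conditions: 2
chromosomes × 10 Mb (1/300 of a human genome), 300 TSS, a 20,000-SNP
background pool with folded MAFs from `0.5·Beta(1.2, 3)` (chip-like skew
toward low frequencies), 20 trait loci, and 2,000 peaks per track with
log-normal lengths (median 250 bp, clipped to [50, 2000] bp) — about
2.5% genome coverage per track, the same order as real DHS tracks
(~87,000 peaks spanning ~25 Mb, just under 1% of a human genome).
Replicates are jittered (±100 bp), thinned (5% dropout) copies of a base
track.

The locus window in the generator defaults to 50 kb rather than the
pipeline's 500 kb.  This is a deliberate scale choice: the real geometry
puts all of a study's loci at roughly 0.2–1.6% of the genome, and at
1/300 genome size a 500-kb window would make 20 loci cover half the
synthetic genome.  In that regime null windows overlap the planted
regions half the time and the planted factor is structurally
unrecoverable (FE → f / (1 + (f−1)·q) with q the trait-span fraction);
at 50 kb the trait loci occupy 5% of the genome and the residual
attenuation is ~2–5%, visible in the acceptance numbers (mean recovered
FE ≈ 1.44 for f = 1.5, ≈ 1.89 for f = 2.0 — within the ±10%
identifiability band, slightly below f for exactly this reason).

Peak planting draws each peak start from a two-component mixture — inside
the trait loci with probability `f·T / (f·T + G − T)` (T trait span, G
genome size), uniform within the chosen component — so the expected
within-locus start density is exactly `f` times background.  Tag SNPs
are drawn from the pool itself with same-chromosome spacing ≥ one window
(disjoint loci by construction; merging is exercised by dedicated unit
tests instead), so every lead SNP is guaranteed a nonempty candidate
pool.

What the generator does **not** emulate: linkage disequilibrium,
chromatin-domain structure, non-uniform gene/SNP density along
chromosomes, realistic GWAS effect sizes, or correlated peak placement
across tissues.  Passing tests therefore demonstrate that the estimator
is calibrated and identifies planted enrichment under matched, uniform
geometry — not that any particular real tissue–trait association would
reach a given AFE.  Real-scale headline numbers (hundreds of tracks,
dozens of catalog studies) are outside desk scale by design.

## Numerical choices

* Overlap counts use two binary searches per query against independently
  sorted peak-start and peak-end arrays (`#starts < E` − `#ends ≤ S`);
  a brute-force O(n·m) scan serves as the oracle in tests.
* All internal coordinates are 0-based half-open; GWAS, pool and TSS
  table positions are 1-based only in files.
* Floats are serialised via shortest-round-trip `repr`, making write/read
  round trips exact and reruns byte-identical.
* Per-study null-sampling seeds derive from the master seed and the
  study's rank in sorted study-id order, so results are independent of
  processing order and reproducible end to end.
* Degenerate inputs: a zero null mean leaves the fold undefined (NaN,
  flagged) with p = 1/N if anything was observed and p = 1 otherwise;
  replicates with undefined folds are excluded from the AFE with a
  warning; empty results tables are write errors, and empty BED files
  parse to empty tracks with a warning.

## Problem sizes

Test-suite and acceptance runs use the desk-scale defaults above with
500–50,000 null sets depending on what the check needs: the p-floor
check needs the full 50,000 (the floor is the quantity under test),
calibration uses 200 runs × 1,000 sets, and recovery uses 50 runs × 500
sets per factor, which bounds the Monte-Carlo SE of the mean FE near
0.02 — small against the ±10% band.

## Known limitations

* The representative SNP of a merged locus is its first-reported member;
  if reporting order is meaningless in an input catalog, the choice is
  arbitrary (but deterministic).
* Whether the inclusion filter's locus count should be taken before or
  after neighbor-merging is a judgement call; merged counts are the
  default ("independent loci"), with `use_merged_counts=False` for the
  raw row count.
* The minimum-p tissue summary is anti-conservative across replicates;
  treat `summary_p` as a ranking device, not a calibrated p.
* Candidate matching is exact-bin: a tag SNP near a bin edge draws
  candidates only from its own bin, which is faithful to the stratified
  design but discards near-boundary candidates.
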