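# Methods

This note documents the models, parameter choices, numerical rules and
known limitations of `selandscape`, in the order the pipeline runs.

## Coordinates and overlap

All coordinates are 0-based half-open (BED convention); overlap means
≥ 1 shared bp. Chromosome names are matched verbatim — no `chr`
normalization — so inputs must agree on naming. bedGraph tracks are
expanded to per-bp arrays; overlapping records resolve
last-writer-wins with a counted warning, a pragmatic choice for a
dialect the format itself leaves unspecified. Signal values are held
as float32 (coverage-scale data; the ~7 significant digits are far
below ChIP noise).

## Super-enhancer calling

The procedure follows the standard H3K27ac stitching recipe:

1. **Promoter exclusion** (`tss_exclusion`, default ± 2.5 kb, 0
   disables): peaks *fully contained* in any TSS window are removed
   before stitching (filter-then-merge). The alternative
   merge-then-mask is not implemented; filter-then-merge is the
   simplest faithful reading and is what the brute-force oracle in the
   tests checks.
2. **Stitching** (`stitch_distance`, default 12.5 kb): peaks whose gap
   is ≤ the distance merge, per chromosome, order-independently.
3. **Quantification**: signal = Σ chip − Σ input over the stitched
   span, floored at 0. Total summed coverage (not density) is used, so
   ranking is additive in constituent signal; both input-subtracted and
   chip-only modes are supported because re-analyses differ in whether
   an input track exists per sample.
4. **Cutoff**: sort signals ascending, scale rank and signal to
   [0, 1], take `i* = argmax(x − y)`. For a convex ascending curve
   this is the tangent-slope-1 point of the hockey stick. Ties break
   toward the highest index, i.e. toward *fewer* super-enhancers — a
   deterministic rule that a brute-force search can verify exactly. A
   landscape of all-equal signals is degenerate: the cutoff is the
   maximum, zero SEs, with a warning. The cutoff index is invariant to
   affine rescaling of the signal vector.
5. **Gene assignment** (`assignment_window`, default 50 kb): a gene
   links to an enhancer if its body overlaps the region (relation
   `overlap`, distance 0) or its TSS lies within the region ± window
   (relation `proximal`, distance = gap from region edge to TSS).
   Published SE studies rarely state their assignment rule; ours is
   recorded in the outputs rather than asserted as anyone else's.
   Enhancer strand is ignored; gene strand only locates the TSS.
6. **Consensus** across a cohort: a gene is nominated if SE-assigned
   in ≥ `min_cell_lines` cell-line samples and ≥ `min_tumors` tumor
   samples (defaults 3 and 1, the recurrence rule used for SE-driven
   oncogene screens). The operation is monotone: adding a membership
   never removes a nominated gene.

## SE/TE association statistics

* **Containment chi-squared**: 2×2 table of regions with/without ≥ 1
  TF peak, SE rows vs TE rows, Pearson chi-squared with df 1 and *no*
  Yates correction (available as a flag). Zero margins raise with a
  pointer to the Fisher test.
* **Peak-set co-localization**: the genome is tiled into disjoint
  windows (default width = median peak width of the union set, a scale
  at which one window rarely holds two peaks of the same set); each
  window is classified by (hit by A, hit by B) and the 2×2 window
  table is tested with the two-sided Fisher exact test. Reciprocal
  peak-level overlap counts use the ≥ 1 bp rule with each peak of the
  query set counted once, and are printed to the nearest percent; the
  window-null construction is recorded in the output metadata because
  published figures typically omit theirs.
* **Direct targets**: bound (≥ 1 TF peak within TSS ± `bind_window`,
  default 50 kb, or overlapping the gene body) *and* responsive
  (|log2FC| > `fc_threshold`, default 1.0 — i.e. changed more than
  2-fold in either direction) on knockdown. Genes lacking expression
  data are reported in an `untested` side channel, never silently
  dropped. Co-occupancy of a second TF over the direct-target list
  uses the same binding rule and is reported to one decimal percent.

## GGAA microsatellite scanning

Maximal runs of consecutive `GGAA` (forward) or `TTCC` (reported as
minus-strand GGAA) units with ≥ `min_units` units (default 4 — the
literature never pins the unit threshold, so it is config-exposed and
recorded; a sensitivity sweep over 2–6 is a one-line loop). Matching
is exact; `N` terminates runs; the scan is leftmost-greedy, so
same-strand runs are disjoint and non-extendable, matching a
`(GGAA){k,}` regular-expression oracle exactly. Degenerate-unit
tolerance and PWM scanning are out of scope.

## Response enrichment

* **log2FC**: each replicate column is scaled to counts per million;
  log2((mean treated CPM + 1)/(mean control CPM + 1)). The
  pseudocount of 1 CPM stabilizes low counts; normalization is
  declared in output metadata. Note CPM renormalization makes the
  estimator exactly antisymmetric under swapping conditions but biases
  it when the perturbation shifts most of the library (a global
  repression shrinks the treated library, inflating treated CPM): the
  effect-recovery guarantee (mean bias < 0.1) holds for effect
  distributions centered near zero, and rank-based downstream
  statistics are unaffected by the common shift.
* **Sensitive set**: genes with log2FC < −log2(threshold_fold),
  strict, matching the "decreased over 2-fold" phrasing.
* **GSEA**: classic weighted running sum on the descending fold-change
  ranking (ties broken lexicographically by gene id so results are
  bit-reproducible). `weight_p` defaults to 1.0; 0 (unweighted KS) is
  supported. The null permutes gene-set labels — with a single
  preranked fold-change vector there is no phenotype to permute — by
  drawing `n_perm` (default 1000) random sets of equal size. The
  nominal p is sign-conditional, `(1 + #{same-sign null ≥ |ES|}) /
  (1 + #same-sign null)`, which is uniform under the null (verified by
  KS calibration in the suite); dividing the same-sign count by all
  permutations instead would cap p near 0.5. NES divides ES by the
  mean |same-sign null ES|. The leading edge is the set members at or
  before the extremum (after it, for negative ES). Sets larger than
  half the universe trigger a degeneracy warning.
* **Distribution comparison**: two-sided Wilcoxon rank-sum via the
  Mann–Whitney U with tie correction; exact null for small tie-free
  samples, normal approximation otherwise; medians reported alongside.
* Multiple gene sets get Benjamini–Hochberg q-values; cross-collection
  FDR batteries and dispersion-modelled differential expression are
  non-goals — the fold-change summary feeds ranking statistics, not
  per-gene inference.

## Synthetic data: what it emulates, and what not

`SimConfig` defaults define the study conditions: 2000 enhancer units
on a 4 × 10 Mb genome, 20 planted SE clusters of 3–8 peaks at 10×
amplification over the background median; TF placement probabilities
0.8 (SE unit) vs 0.1 (TE unit) plus 600 total peaks with the rest
intergenic; GGAA run rates 0.5 vs 0.05 runs/region, k ~ U{4..12};
negative-binomial counts (mean 100, dispersion 0.1, var = m + αm²,
3 + 3 replicates) with log2FC effects N(−1.5, 0.5) for SE genes vs
N(−0.3, 0.5) otherwise — a strong-vs-mild repression contrast of the
kind transcription-inhibition experiments produce.

Design choices worth knowing:

* **Winsorized log-normal background** (σ = 0.25, capped at μ + 2σ).
  An unbounded log-normal tail places the tangent-slope-1 point *inside*
  the background tail: the expected order-statistic spacing
  σ·s/(N·φ(z)) crosses the slope-1 threshold S_max/N around z ≈ 2
  for any σ, so dozens of background units would be called super and
  planted-truth recovery would be ill-posed. The cap represents
  saturation of the background signal scale and pins the knee of the
  hockey stick to the background/planted boundary. Consequence:
  recovery claims hold for landscapes whose background tail is tamer
  than the planted contrast — which is precisely the planted-truth
  regime, not a claim about any real tumor's tail shape.
* **One TF Bernoulli per stitched unit**, not per constituent.
  Per-constituent placement makes a multi-constituent SE contain a peak
  with probability 1 − (1 − p)^k even at equal rates, so the
  "equal-rate" configuration would not be a null for the region-level
  containment test (measured: 50/50 spurious rejections). One draw per
  unit (landing in a random constituent) makes equal rates a true null
  while the default 0.8/0.1 contrast still produces strong enrichment.
* **Tracks are synthesized from peak scores** (rectangular pulses of
  height score/width over a 0.05 noise floor, constant 0.02 control),
  not from simulated reads — sufficient to exercise quantification and
  orders of magnitude faster. Read-level artifacts (mappability, GC
  bias, fragment-size smearing) are not modelled, so passing tests say
  nothing about robustness to them.
* **Planted SE genes share ids across cohort samples** (`SEG####`),
  emulating recurrently SE-driven genes so consensus nomination has a
  recoverable truth; background genes are per-sample noise. Gene TSSs
  sit 5–10.5 kb from their anchor unit — inside the assignment window,
  outside the promoter-exclusion window, and short of the minimum
  inter-unit gap, so gene placement never deletes constituent peaks.
* **Seeding**: one global seed fans out to per-stage child generators
  (keyed by stage name), so any stage can be regenerated independently
  and all outputs are byte-identical across runs.

## Problem sizes in the test suite

The suite exercises: planted-SE recovery at the full default scale
(2000 units × 20 seeds); GSEA planted-shift detection at 5000 genes ×
50 seeds with 200 permutations per run; null calibration with 200
permutation draws and 50 equal-rate landscapes at 400 units; the
repeat-rate contrast at 200 + 2000 regions; and exact-oracle
comparisons (running sums ≤ 20 genes, 1000 random 2 kb sequences,
2×2 tables with ≤ 200 windows). These sizes keep the whole suite
around a minute while leaving every statistical check at the scale its
guarantee is stated for.

## Known limitations

* The hockey-stick cutoff is a geometric rule; on landscapes with very
  heavy background tails it calls the extreme background tail super,
  which is a property of the method, not a bug in the implementation.
* Consensus nomination compares gene *ids* across samples; it assumes
  one shared annotation (or, in simulation, the planted id scheme).
* The Fisher window null treats windows as exchangeable; strong
  peak-density covariates (chromatin accessibility, mappability) are
  not modelled.
* `compute_log2fc` is a moment estimator with CPM normalization — no
  shrinkage, no dispersion modelling; see the bias note above.
* Hi-C loop calling, motif discovery (beyond GGAA runs), GO analysis
  and read-level processing are explicitly out of scope.
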