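# Methods

## The benchmarking model

`dabench` evaluates two-group differential-abundance tests by *resampling
with effect injection* rather than by scoring methods on data simulated
straight from a parametric alternative. One benchmark replicate is built
from a fixed reference count matrix as follows:

1. **Group sampling.** m₁ + m₂ columns are drawn uniformly without
   replacement and their order randomized; the first m₁ form group A.
   Replicate-to-replicate variation therefore comes from which samples are
   drawn, exactly as it would in a resampling study on real cohorts.
2. **Gene filter.** A gene is removed iff strictly more than 75 % of its
   resampled cells are zero, or its mean count is strictly below 3.
   Boundary cases (exactly 75 % zeros, mean exactly 3) are kept. The
   statistics are computed on the resampled columns, not the full
   reference, because the filter exists to guarantee that thinning has
   fragments to act on *in this replicate*. The filter can be disabled to
   study unfiltered behaviour.
3. **Stratification** into low/mid/high abundance bands on the pre-effect
   mean count. Cutoffs are user-set; presets (500, 5000), (50, 500) and
   (10, 50) cover deep-shotgun and pyrosequencing-scale data. Gene mean <
   low_hi → low, low_hi ≤ mean ≤ mid_hi → mid, mean > mid_hi → high.
4. **Truth assignment.** round(0.10 · n) genes are drawn uniformly to be
   differentially abundant (the fraction is configurable; 0 yields a null
   benchmark for p-value studies).
5. **Effect injection by binomial thinning.** For each DA gene one group
   is chosen and every count y in it is replaced by an independent
   Binomial(y, 1/q) draw, so E[y*] = y/q and the group mean drops by the
   fold-change q while integer counts, zeros and the mean–variance
   relation of count data are preserved. Thinning never increases a count,
   and null genes are bit-identical before and after injection — both are
   tested invariants.

**Direction of the effect.** The thinned group is drawn independently per
DA gene by default (`direction_rule="per_gene"`), giving effects in both
directions within one dataset; a `fixed_group` option thins the same group
for every DA gene. The per-gene default was chosen as the more realistic
and the more symmetric of the two defensible readings.

## The synthetic references

Because the evaluation must run without any external download, the
reference matrices are themselves synthetic, drawn from a zero-inflated
negative binomial:

* library sizes D_j ~ LogNormal with mean `mean_depth` and CV `depth_cv`
  (default 0.6 — metagenomic libraries routinely vary several-fold);
* relative abundances a_i ~ LogNormal(0, `abundance_log_sd`), renormalized;
  the log-sd (1.5 pyro-like, 2.0 illumina-like) produces the heavy tail in
  which a minority of genes holds most fragments;
* counts y_ij ~ NB(mean a_i·D_j, dispersion α) with Var = μ + αμ²;
  α = 0.3–0.5 puts the biological coefficient of variation at 0.55–0.7,
  the order observed between unrelated human gut donors. α = 0 is the
  exact Poisson limit (tested against the variance = mean law);
* extra dropout with probability `zero_inflation_max · exp(−a_i·mean_depth/τ)`,
  concentrating excess zeros in low-abundance genes as seen in short-read
  data binned against de-novo assemblies.

Presets: `pyro_like` (2 150 genes × 110 samples, 155 890 fragments/sample,
mild zero inflation) and `illumina_like` (3 029 genes × 120 samples,
strong zero inflation; depth 1 M by default, with a flag restoring the
literal 62.5 M of the deep-shotgun study it emulates — the relative
structure, not the absolute depth, is what the benchmark exercises).

The negative-binomial family was chosen deliberately: overdispersion is
the documented failure mode that separates pooled-count tests from
per-sample tests, so the generator must produce Var > μ. What the
generator does **not** emulate: gene–gene correlation, sample-specific
distributional heterogeneity, compositional coupling between genes, or
technology-specific artefacts. Passing benchmarks here therefore
demonstrates correct machinery and the expected qualitative ordering of
methods under overdispersion and zero inflation — not performance on any
particular real cohort.

## The native tests

All methods share the convention: effects are log2 fold-changes of group 2
relative to group 1 (groups ordered by first appearance in the design), so
relabeling negates estimates and leaves p-values unchanged (a tested
invariant for every method).

* **Poisson GLM** — log-linear model counts ~ group with offset log N_j.
  For this saturated two-group design the MLE is closed-form (fitted group
  rate = pooled count / pooled library size; Var(β̂) = 1/x₁ + 1/x₂), so
  the implementation is vectorized across genes and agrees with an
  iterative GLM fit to numerical precision (cross-checked against an
  independent GLM implementation in the tests). Wald z by default, LRT
  χ²₁ as an option.
* **Quasi-Poisson GLM (OGLM)** — same mean model; gene-specific dispersion
  φ = Pearson X²/(m−2), standard error scaled by √φ, Wald t with m−2 df.
  No shrinkage across genes, by design. φ may optionally be floored at 1;
  the default leaves it free, matching the plain quasi-likelihood recipe.
* **Fisher's exact / exact binomial on pooled counts** — the 2×2 table
  [[x₁, T₁−x₁], [x₂, T₂−x₂]] and x₁ ~ Bin(x₁+x₂, T₁/(T₁+T₂))
  respectively. Both use the minimum-likelihood two-sided convention (sum
  of outcomes whose point probability ≤ the observed one), matching R's
  `fisher.test`/`binom.test`; both are verified against exhaustive
  enumeration oracles.
* **t-tests** — on counts divided by column totals and rescaled by the
  mean library size ("normalized counts" on a count-like scale, so the +1
  pseudo-count of log(y+1) is meaningful), optionally √y or log(y+1)
  transformed; pooled-variance Student or Welch.
* **Wilcoxon–Mann–Whitney** — on normalized counts; the exact rank-sum
  null distribution when a gene has no tied values (verified against full
  permutation enumeration), otherwise the tie-corrected normal
  approximation with continuity correction, mirroring `wilcox.test`.

**Degenerate genes.** A statistic can be undefined (zero pooled counts in
one group for the GLMs; zero variance in both groups for the t-test).
Such genes get missing (NaN) p-values, are ranked last in every ROC/FDR
computation, and are never called at any FDR threshold — deterministic
and documented rather than silently dropped.

## Evaluation machinery

* **ROC.** Genes sorted by ascending p; tied p-values (including the
  missing-value block) advance as one block, contributing a single
  diagonal segment; curve anchored at (0,0) and (1,1). Ties are the only
  genuinely open convention here; block advance is deterministic and
  order-independent.
* **AUC.** Trapezoid integral; AUC₀.₀₅ linearly interpolates the curve at
  FPR = 0.05 and divides by 0.05. Perfect ranking gives exactly 1, a
  diagonal gives 0.025.
* **Consensus ROC.** Fixed grid of 1001 equispaced FPR values; each
  replicate contributes its TPR at the largest achieved FPR ≤ the grid
  point (right-continuous step interpolation — the conservative choice
  between step and linear); the consensus is the pointwise mean.
* **qq summaries.** Each null replicate subsampled without replacement to
  exactly 1500 p-values so replicates of different post-filter size are
  comparable; sorted values against plotting positions (i−½)/N; mean
  across replicates; pooled histogram counts alongside.
* **FDR.** Estimated FDR is the BH estimator n·p(k)/k with the standard
  step-up monotonization (cumulative minimum from the largest rank, capped
  at 1) — i.e. `p.adjust`-equivalent adjusted p-values, verified against a
  brute-force oracle. True FDR at rank k is (false calls up to k)/k.
  `confusion_at_fdr` optionally subsamples 1500 genes (recomputing BH on
  the subsample) before thresholding, for cross-replicate comparability;
  the subsample is on by default in sweep runs and skipped when a dataset
  is already smaller.
* **Effect-size bias** is measured on DA genes only, orienting each
  estimate by the thinned group so a perfect recovery equals +log2 q; an
  optional mean-count floor restricts to well-observed genes where the
  residual bias reflects the estimator rather than sampling noise.

## Experiment runner

Replicate seeds are derived as SeedSequence(master, m₁, m₂, ⌊1000q⌋, rep),
so every (condition, replicate) cell is reproducible in isolation and
adding conditions to a plan never changes existing cells. Failures are
caught per (method, replicate), recorded in the manifest, and never abort
a sweep. The reference matrix is generated (or loaded) once per plan;
resampling alone provides replicate variation. Reports are plain TSV plus
a Markdown summary; reruns with the same master seed are byte-identical
(tested).

## Problem sizes

The shipped test-suite and acceptance-script runs use the `pyro_like`
reference (2 150 × 110, ~156 k fragments/sample) with 15–100 replicates
per condition, and 3 000-gene parametric nulls for calibration checks —
sizes at which every reported quantity is stable to well within the
tolerances asserted, while a full suite run stays in the minutes range on
one core. Larger sweeps (more replicates, `illumina_like` at literal
depth) are configuration changes, not code changes.

## Known limitations

* Exact-test p-values for very deep pooled counts rely on SciPy's
  hypergeometric/binomial tail routines; they are exact but the per-gene
  loop dominates sweep runtime for those two methods.
* The WMW exact path requires complete absence of ties within a gene;
  with count data and small depth, most genes take the tie-corrected
  normal path, as the corresponding R function would.
* The quasi-Poisson dispersion estimate has only m−2 df at small group
  sizes; its t-reference is the standard quasi-likelihood approximation,
  not an exact distribution.
* No between-method significance testing is provided; the framework ranks
  methods, it does not test whether two AUCs differ.
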