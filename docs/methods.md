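# Methods

## Problem setting

`shufflepower` analyses two-group RNA-seq count tables — the motivating
design is a rat dietary study with four control-diet (CD) and four
high-fat-diet (HFD) germ-cell samples, with counts aggregated per
annotation class (protein-coding genes, miRNAs, piRNAs, repeat classes).
It answers two questions jointly: *is anything differentially expressed?*
and, when the answer is "almost nothing", *was the design powerful enough
that we would have seen it?* The second question is addressed by a
shuffle-based spike-in power analysis rather than an analytical power
formula, because the relevant power depends on the empirical mean and
dispersion spectrum of the actual data.

## Differential expression model

Counts for annotation *i* in sample *j* are modelled as negative binomial
(NB) in the mean/dispersion parameterisation,

    K_ij ~ NB(mu_ij, alpha_i),    Var = mu + alpha * mu^2,

with a log-linear mean

    log mu_ij = log s_j + beta0_i + beta1_i * x_j,

where `s_j` is the sample size factor, `x_j` the 0/1 diet indicator
(CD = 0, HFD = 1), and `beta1_i / ln 2` the log2 fold change (log2FC),
reported as HFD relative to CD everywhere. The diet coefficient is tested
with a Wald test (H0: log2FC = 0) against the standard normal, and
p-values are adjusted with the Benjamini–Hochberg (BH) step-up procedure.
Testing, filtering, normalisation and BH multiplicity are all performed
separately within each annotation class.

Pipeline stages and their conventions:

- **Filtering.** Annotations with raw mean count below 1 across all
  samples are excluded; the boundary is inclusive (mean exactly 1 is
  kept).
- **Size factors.** Median-of-ratios: per-sample medians of
  count/geometric-mean ratios over annotations with positive geometric
  mean, rescaled to geometric mean 1. When no annotation is positive in
  every sample, reference geometric means are computed over positive
  counts only, restricted to annotations detected in at least half the
  samples.
- **Dispersion.** Per-annotation method-of-moments estimates using
  within-group pooled variance on normalised counts (pooling within
  groups keeps genuine fold changes from inflating dispersion), a
  hyperbolic trend `alpha(mu) = a0 + a1/mu` fitted by Huber robust
  regression over informative annotations, and shrinkage of gene-wise
  estimates toward the trend by a weighted geometric average (weight 0.5
  on the trend by default). Two moderation rules follow from the small
  residual degrees of freedom of a 4 + 4 design: (i) annotations whose
  moment estimate is at the numerical floor (negative raw estimate)
  take the trend value directly, and (ii) the final dispersion is never
  allowed below the trend. Without rule (ii) the null Wald test is
  anti-conservative at n = 4 + 4 (the below-trend half of the 6-df
  gene-wise estimates is sampling noise, and plugging it in understates
  the standard errors); with it the raw p < 0.05 fraction sits at the
  nominal level in null simulations. Dispersions are floored at 1e-8.
- **GLM fitting.** Vectorised iteratively reweighted least squares
  across all annotations simultaneously (shared design matrix, per-gene
  weights), at most 100 iterations, convergence when the largest
  coefficient change falls below 1e-8; linear predictors are clipped at
  ±50 to keep degenerate rows (e.g. all-zero groups) finite, and
  non-converged fits are flagged and assigned p = 1 rather than raised.
  The fitter is checked in the test suite against a dense NB likelihood
  grid search and against statsmodels' NB GLM.
- **Effect sizes are unshrunk MLEs.** No Bayesian moderation of the
  log2FC is applied; the test and its operating characteristics, not the
  point estimate's posterior shrinkage, drive every downstream result.
- **Significance.** `alpha_sig` defaults to 0.05 on the BH-adjusted
  p-value and is exposed as a flag, since reasonable defaults differ
  between conventions (0.05 global alpha vs 0.1 in some DE frameworks).

## Homogeneity diagnostics

- **VST.** The closed-form NB variance-stabilising map
  `v(x) = (2/sqrt(a0)) * asinh(sqrt(a0 * x))` on size-factor-normalised
  counts, with `a0` the fitted trend intercept, affinely rescaled so that
  `v(x) -> log2(x)` at high counts. It is strictly monotone, maps 0 to 0
  before rescaling, and falls back to `log2(x + 1)` if the trend
  intercept is unusable. This is an analytically testable stand-in for
  spline-based VSTs: it satisfies the same stabilising contract (the
  spread of transformed values is approximately mean-independent) and its
  defining property is asserted by simulation in the tests.
- **Correlation clustering.** Between-sample Pearson correlations r on
  VST values; average-linkage (UPGMA) clustering at distance `1 - |r|`
  (so perfectly anti-correlated samples are "close"; heights live in
  [0, 1]). Zero-variance samples have undefined correlations and are
  dropped greedily (worst offender first) before clustering.
- **PCA.** Per-annotation centring and unit-variance scaling across
  samples (the convention of R's `prcomp(scale = TRUE)`), zero-variance
  annotations dropped, then SVD. Signs are fixed deterministically: the
  largest-magnitude loading of each component is positive.
- Two scalar summaries support simulation tests: the within-group minus
  between-group mean correlation (≈ 0 under homogeneity) and a PC1
  diet-separation indicator (all samples of one group strictly on one
  side).

## Shuffle-based power analysis

A simulated ("spiked") annotation is built by pairing the CD block of
counts from one randomly chosen real annotation with the HFD block of
another — equivalently, permuting annotation labels independently within
each treatment-group block. Counts are therefore moved, never altered:
within each group block every spiked count vector is an exact copy of a
host annotation's block, and the experimental design (4 + 4, library
depths, mean/dispersion spectrum) is preserved by construction. Each
spike's realised log2FC is the log2 ratio of its size-factor-normalised
group means with a pseudocount (default 0.5) added to both means; spikes
are retained while `|log2FC|` lies in a class-specific window
(0.0–2.0 for protein-coding genes, 0.0–0.5 for miRNAs in the motivating
design), until a target count is reached or an iteration cap is hit
(a short set is returned with a warning).

Retained spikes are appended to the real table under reserved
`SPIKE_`-prefixed ids, inheriting the host class, and the *entire* DE
pipeline — size factors, dispersions, Wald tests, BH — is re-estimated
on the combined table, exactly as a real analysis would see it. Spikes
that fall below the low-count filter of the combined run count as
tested-and-missed (denominator, not detected), so starving a bin of
low-count spikes cannot inflate its power.

**Power curve.** Power is aggregated in |log2FC| bins of width exactly
0.1: power per bin = significant spikes in bin / all spikes in bin.
Empty bins have undefined (NaN) power, never zero. Two overall
proportions are also reported, because "proportion of significant
simulated annotations" admits two denominators: all retained spikes, and
all tested annotations of the class.

**Minimal detectable effect.** `detectable_effect` returns the midpoint
of the lowest non-empty bin whose power, and the power of every higher
non-empty bin, reaches the threshold (default 0.8 — a conventional
choice, exposed as a parameter). Empty bins are skipped when checking
the "every higher bin" condition; if no bin qualifies the result is NaN
with a warning.

## Synthetic data generator

The generator emulates the features of the motivating data that the
pipeline's statistics depend on:

- class-structured annotation universes (defaults 2,000 protein-coding
  and 300 miRNA rows — desk-scale stand-ins for the published 18,025 and
  285; full scale is one config field away);
- n = 4 samples per diet group (configurable, ≥ 2);
- a log10-normal baseline mean spectrum (`mean_log_mu = 1.5`,
  `sd_log_mu = 1.0` by default), spanning several decades and placing
  roughly 7% of annotations below the mean-count-1 filter so the filter
  is exercised;
- NB overdispersion decaying with the mean, `alpha(mu) = a0 + a1/mu`
  with defaults `a0 = 0.05`, `a1 = 2.0` (dispersion ~0.25 at mean 10,
  ~0.05 at mean 1,000 — a realistic bulk RNA-seq profile);
- optional true DE: a configurable fraction of annotations receives a
  log2FC drawn uniformly from ±[lo, hi] with random sign;
- per-sample relative depth multipliers;
- a paired ground-truth table (true mean, log2FC, dispersion per
  annotation) and full seed determinism (same seed ⇒ bit-identical
  output; the seed is recorded in the matrix metadata).

What it does **not** emulate: count correlation between annotations
(co-expression), GC/length biases, outlier samples, batch structure, and
any calibration to a specific deposited dataset — the simulated spectrum
is a structural stand-in, not a fit to real counts. Passing tests
demonstrate the pipeline's operating characteristics (calibration, FDR
control, recovery, power monotonicity) under the NB model it assumes,
not robustness to violations of that model.

## Numerical choices and degenerate inputs

- NB draws use the exact gamma–Poisson mixture; dispersions below 1e-12
  fall back to Poisson.
- BH is implemented directly (sorted step-up with reverse cumulative
  minimum) and cross-checked against brute-force enumeration and
  statsmodels in the tests.
- Zero-variance annotations get floor dispersion, not an error; all-zero
  annotations survive fitting via the clipped linear predictor and come
  back flagged.
- The trend fit requires ≥ 10 informative annotations; otherwise
  per-annotation estimates are used and a warning logged.
- Problem sizes in the test and acceptance runs (2,000-gene tables,
  1,500–2,000 spikes, 10–20 seeds per operating characteristic) were
  chosen as the smallest sizes at which the Monte-Carlo error of each
  measured quantity is comfortably below its assertion band.

## Known limitations

- The dispersion moderation (trend floor) is deliberately conservative:
  genes that are genuinely *under*-dispersed relative to the trend are
  tested with trend dispersion, costing a little power at those genes in
  exchange for calibration of the family as a whole.
- The Wald test relies on asymptotic normality of the coefficient; at
  very low counts (normalised means below ~10) it is conservative-to-
  erratic, which is the usual behaviour of unshrunk NB Wald tests at
  n = 4 + 4.
- Only two-level, single-factor designs are supported; no continuous
  covariates, outlier-count handling (Cook's distance), or independent
  filtering.
- The power analysis inherits the fold-change estimator of its window
  rule: a spike's realised log2FC is computed with a pseudocount, so at
  very low counts the realised and asymptotically estimable effects can
  differ slightly; bins are populated by the realised value.
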