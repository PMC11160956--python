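# Methods

This note documents the statistical procedures implemented in `retrep`,
the synthetic data-generating model used to exercise them, the numerical
conventions, and the design choices made where more than one reasonable
convention exists.

## Estimators

### Variance decomposition and ICC

For one method and one cohort, each eye's true value is estimated by the
mean of its usable images; `sd_between` is the sample SD (n − 1
denominator) of those per-eye means over eyes. `sd_within` is the pooled
within-eye sample SD: the square root of the per-eye sample variances
averaged with weights equal to their degrees of freedom (the standard
one-way layout). Eyes with a single usable image contribute their value
to `sd_between` but nothing to `sd_within` — this uses all data for the
between-eye spread without fabricating a within-eye variance; the count
of such eyes is logged.

The ICC is `sd_between² / (sd_between² + sd_within²)`, computed as a
property of the decomposition object so the identity
`ICC = 1 / (1 + (sd_within/sd_between)²)` holds exactly by construction.
The *adjusted* ICC replaces the between-eye SD with a reference SD
estimated on a broader population (here: all supplied cohorts pooled) in
**both** occurrences — numerator and denominator — which is the only
substitution consistent with the ICC formula itself; a young, healthy
cohort has an artificially small between-eye spread, and the adjusted
value answers "how precise is this measurement relative to a
heterogeneous population".

Note that `sd_between`, being the SD of per-eye means of noisy
measurements, is inflated by `σ_w²/n̄` relative to the true between-eye
SD; at the many-images-per-eye designs analysed here this bias is small
(≈ 0.4% of the ICC at 10 images per eye and a noise ratio of 0.5) and is
accepted rather than corrected, since the estimator is meant to mirror
standard practice.

### Correlations and the random-pairing resampling

Pearson and Spearman correlations are computed by one shared row-wise
kernel (centred cross-products); Spearman is Pearson applied to average
ranks. This matters for the resampling: with the single-pair path and
the 20,000-replicate path sharing bit-identical arithmetic, a cohort
with exactly two images per eye — where every replicate necessarily
draws the same pairing — returns the first/last correlation *exactly*,
with a zero-width interval. Tests verify the kernel against an
independent textbook sum-formula implementation to 1e-12.

Each resampling replicate draws, per eye, an unordered pair of two
distinct images uniformly at random (stored in time order; correlation
is symmetric, fixing the order only fixes the floating-point path). The
reported estimate is the median over replicates; the interval is the
empirical 2.5/97.5 percentile (linear interpolation). The percentile
interval for Pearson can have inaccurate coverage — resampling intervals
for correlations are known to — and the summary output repeats this
caveat. p-values use the t approximation with n − 2 degrees of freedom,
two-sided, for both statistics.

### λ, quality sweeps and the logit scale

λ is the within-eye sample SD divided by the reference between-eyes SD,
in percent. The reference SD defaults to the pooled (combined-cohort)
between-eye SD so that λ is comparable across datasets; a per-cohort
reference is available by passing `reference_sd` explicitly. Eyes with
fewer than two usable images are reported ineligible rather than given
λ = 0, which would understate their noise. Each λ carries the *worst*
P(bad) among the images used, because the SD's squaring makes a single
bad image dominate, so the maximum — not the mean — quality is the
relevant covariate. Quartiles use linear interpolation.

The exclusion sweep ranks all images in the cohort by P(bad) descending
(ties broken by image id) and removes the worst ⌈f·N⌉ for each fraction
f ∈ {0, 0.05, …, 0.50}; the ceiling guarantees any nonzero fraction
removes at least one image. Exclusion is cohort-global by quality rank,
not a per-eye quota. The reference SD is *not* re-estimated after
exclusions, so λ stays comparable across sweep rows; a test checks the
f = 0 row is bit-identical to the standalone λ distribution. Eyes
falling below the image floor (default 2) drop out of that row's
distribution; a row with no eligible eyes is flagged (NaN) rather than
fatal.

λ–quality correlations are computed on the probability scale and on
`logit(p) = ln(p/(1−p))` with p clipped to [1e-6, 1 − 1e-6] (the
analysis receives probabilities, not the quality model's raw logits, so
the clip guards the endpoints). The logistic link is monotone, so
Spearman must agree across scales; the implementation asserts this at
runtime to 1e-12.

### Interchangeability

Two methods are compared on per-eye means over images passing the
quality gate (default P(bad) < 0.8): Pearson, Spearman, and a
Bland–Altman summary (mean difference and limits of agreement
mean ± 1.96 · SD of the per-eye differences). Averaging over images
first reduces measurement noise; a simulation test confirms per-eye
means correlate more strongly between methods than single images do.

## The synthetic data-generating model

No suitable public dataset with many repeated fundus images per eye is
deposited, so the pipeline is exercised on synthetic cohorts with known
ground truth. Per eye, a latent standard-normal truth is drawn and
mapped to each method's scale (`mu_trait + sigma_between · z`), so
multiple methods share the eyes' ranking perfectly in truth and differ
only by calibration and noise. Per image:

* quality `pbad ~ Beta(quality_alpha, quality_beta)`;
* noise SD = `sigma_within_base · (1 + noise_logit_slope · max(0, logit(pbad)))`
  — images better than P(bad) = 0.5 share a common noise floor, and
  noise grows linearly in the logit above it;
* with probability `outlier_prob`, an image with
  `pbad > outlier_pbad_threshold` receives an additional gross error
  `~ Normal(0, outlier_scale · sigma_between)` — an additive error, not
  scaled noise, because single catastrophically bad frames (not broadly
  noisy series) are what dominate real within-eye SDs. Outlier flags are
  shared across methods (the same physical image is bad for both tools),
  with independent error magnitudes;
* in longitudinal designs the truth drifts between visits
  (visit-to-visit steps of SD `drift_sd`, latent trajectory shared
  across methods); same-day images share the drifted truth.

Generated values are floored at 1e-3 because the traits are physically
positive; a gross error that undershoots zero remains a gross outlier.

### Presets and parameter choices

`preset("caledonia-like")`: 26 subjects / 39 eyes, 5–15 images per eye
summing to exactly 377, 1–2 visits, no drift. Method scales use the
eye-level trait SDs of the designs this preset emulates (DART 0.00733,
AutoMorph 0.02421; means 1.75 and 1.58, typical fractal-dimension
magnitudes for the respective tools). Base noise floors (0.0010 /
0.0090) put the median λ in the low single digits / low teens of
percent, the regime the analysis targets. Quality ~ Beta(0.7, 2.2):
mean 0.23, ~6% of images above 0.6 and ~1.8% above 0.8 — mostly decent
research-setting images with a handful of genuinely bad frames per
cohort.

`preset("grape-like")`: 106 subjects / 196 eyes, exactly one baseline
and one follow-up image (392 total), ~18-month visit interval, drift SD
0.012 / 0.030 (roughly a third of the between-eye SD — genuine
vascular change over long follow-up is not measurement noise but is
indistinguishable from it in a two-point design, making this preset the
pessimistic case). Between-eye SDs 0.03653 / 0.08926 (a heterogeneous
clinical population), quality ~ Beta(0.8, 2.0) with a heavier bad tail.

Both presets use `noise_logit_slope = 2.0`, `outlier_prob = 0.95` above
P(bad) = 0.8 and `outlier_scale = 8`. The scale follows from the regime
the generator must reproduce: an eye of ~10 images whose λ reaches
~80% because of two bad frames implies per-image gross errors of
roughly eight combined between-eye SDs. These values were fixed once,
from the qualitative facts above, before the test suite was written.

### What the generator does and does not emulate

It reproduces the *structure* the analysis assumes — between-eye spread,
quality-linked heteroscedastic noise, gross contamination confined to
bad images, longitudinal drift, the two design shapes — with known
parameters, so recovery tests are meaningful. It does **not** attempt to
match any real dataset's exact λ distribution, ICC or correlation
values: real FD errors are not Gaussian, real quality scores are not
Beta, and two real tools differ by more than calibration (their
truth-rankings disagree; here they agree perfectly, so simulated
interchangeability correlations run high). Passing tests therefore
demonstrate that the estimators recover known truth under the assumed
structure, not that any particular instrument attains a particular
repeatability. One visible consequence: the contaminated many-image
preset yields a cohort-internal ICC well below what a clean design
would give, because the dof-weighted pooled within-SD absorbs the
outlier eyes' huge variances while the between-eye SD stays small.

## Numerical conventions

* All SDs use the sample (n − 1) denominator.
* Identical within-eye values short-circuit to SD = 0 exactly, so λ = 0
  iff the values are identical (the floating-point mean of n equal
  values would otherwise leak λ ~ 1e-13).
* Quantiles/percentiles: linear interpolation throughout.
* Timestamp ties within an eye are broken by image id (lexicographic);
  quality-rank ties in the exclusion sweep likewise — both orderings are
  total, so every run is deterministic.
* Result tables are written with `%.17g` floats and round-trip losslessly.
* Random-pair draws and the generator use numpy's PCG64 generator; every
  public entry point takes an explicit seed.

## Problem sizes in the test suite

Recovery tests run at 1,000 eyes × 10 images (λ) and 500 eyes × 10
(ICC), sizes at which the sampling error of the checked statistic is
several times smaller than the asserted tolerance; resampling tests use
the full 20,000 replicates (vectorised, a few seconds); the
contamination and logit-advantage properties use 20 independent
377-image cohorts each, matching the preset's design size.

## Known limitations

* The ICC estimator inherits the small upward bias described above; no
  REML/mixed-model variant is provided.
* The empirical interval of the resampled Pearson estimate is
  descriptive, not a calibrated confidence interval.
* Eyes, not subjects, are the independence unit; two eyes of one
  subject are treated as independent, as the estimation procedure
  defines, and `subject_id` is carried for reporting only.
* The logit transform operates on clipped probabilities; with access to
  a quality model's raw logits, those should be supplied instead.
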