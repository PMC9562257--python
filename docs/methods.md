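# Methods

## Setting and notation

A surveillance cohort of n patients has a binary high-risk-finding status D
with prevalence π (0.26 by default, the published figure for this
population). Each patient carries two markers: a FIT concentration X ≥ 0
(µg Hb/g faeces) and a VOC classifier score S ∈ [0, 1]. A test at cutoff t
calls a patient positive iff the marker value is ≥ t (inclusive by default —
the FIT pathway treats its limit of detection, 3 µg/g, as a usable cutoff;
a strict rule is available via `inclusive=False`).

## Diagnostic accuracy

From the 2×2 confusion table at a cutoff: Se = TP/(TP+FN), Sp = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN). Interval estimates use the Wilson score
interval by default (Clopper–Pearson optional) at the 95% level, via
statsmodels. With the cohort's own prevalence these count ratios satisfy the
Bayes identities

    PPV = Se·π / (Se·π + (1−Sp)(1−π)),   NPV = Sp(1−π) / (Sp(1−π) + (1−Se)π)

exactly; `bayes_predictive_values` evaluates the same identities for any
supplied prevalence. Published accuracy tables often print the
nomogram-style predictive values computed from the two-decimal Se/Sp rather
than the raw count ratios (at the 10 µg/g cutoff the difference is 0.47 vs
0.487); the reproduction path therefore reports the Bayes form from rounded
inputs, while `performance()` keeps the count-ratio definition.

The ROC curve is the polygon of empirical operating points
(1−Sp, Se); AUC is the trapezoidal area with the chance anchors (0,0) and
(1,1) appended, after sorting by false-positive rate (ties by true-positive
rate). No smoothing or binormal fit is attempted, and no AUC interval is
reported. On the eight published FIT operating points this integrates to
0.67.

Display rounding throughout is half-away-from-zero (2 decimals for rates,
whole percents for probabilities); all propagation is in full precision.

## Likelihood-ratio combination

LR⁺ = Se/(1−Sp) and LR⁻ = (1−Se)/Sp multiply pre-test odds to give
post-test odds; probabilities 0 and 1 are fixed points. The posterior after
a negative result equals the FN fraction among test-negatives of the
expected-frequency 2×2 table — an algebraic identity the tests verify
numerically on a parameter grid.

Serial testing computes only the all-negative path (the rule-out triage use
case): update i+1 takes update i's post-negative probability as its prior.
Patients positive at any stage proceed directly to colonoscopy; their
management needs no further probability update, and the corresponding
accounting lives in the cohort-flow module. A `display_rounded_propagation`
flag re-rounds each intermediate probability to a whole percent before the
next update, mimicking hand nomogram reading; the defaults propagate
unrounded values (both reproduce the printed 26% → 3% → 2% chain).

Parallel combination under class-conditional independence gives
Se = 1−(1−Se₁)(1−Se₂) and Sp = Sp₁·Sp₂. The published combined pair for
this problem (Se 0.97, Sp 0.11) is *empirical* — the specificity came from
retraining the (unpublished) score classifier with FIT as an input — so the
module's default route for reproducing it is `mode="supplied"`: the pair is
accepted as a performance input, never re-derived. The independence product
reproduces the combined sensitivity (0.97) but not that specificity
(0.69 × 0.79 ≈ 0.545), which is documented rather than forced.

## Cohort flow and number needed to scope

Each strategy is an expected-frequency decision tree on n patients (n = 1000
by default). A single-stage strategy: positives = n·π·Se + n(1−π)(1−Sp),
detected = n·π·Se, missed = n·π(1−Se). The serial strategy applies the
second test to the first stage's negatives, with the diseased subset equal
to the first stage's missed count; colonoscopies are the positives of both
stages; NNS = colonoscopies / detected, reported as the nearest integer
(the exact ratio is retained).

Reported cells are rounded half-away-from-zero to integers, and the second
stage operates on the **rounded** first-stage counts. This is deliberate:
it is the only protocol that reproduces all published per-1000 cells
simultaneously (stage-2 detected is round(16 × 0.54) = 9; propagating the
unrounded 15.6 would give 8). The unrounded tree is kept on every row, where
detected + missed = n·π holds exactly, the flow at 10n is exactly 10× the
flow at n, and missed/negatives equals the Fagan post-negative probability —
cross-module identities the tests assert.

Colonoscopy is treated as a perfect gold standard (the positive branch
always ascertains disease status). Cost-effectiveness is out of scope.

## Synthetic cohort calibration

No per-subject data are published, but the accuracy tables pin down
exceedance probabilities P(marker ≥ t | class) at several cutoffs. The
generator fits minimal two-parameter class-conditional families through two
anchors per class:

- **FIT ~ log-normal(μ, σ).** Right-skewed and non-negative, consistent with
  the published mean (SD) of 44.91 (124.13) µg/g. The anchor equations
  ln t = μ + σ·Φ⁻¹(1−p) are linear in (μ, σ): closed form, residual < 1e−8.
  Anchors: diseased (10, 37/68), (80, 17/68); healthy (3, 64/187),
  (10, 39/187) — confusion counts preferred over rounded rates.
- **VOC score ~ Beta(a, b).** Bounded support; the two survival-function
  equations are solved numerically for (log a, log b) (hybrid Newton, several
  starts, residual < 1e−6). Anchors: diseased (0.88, 0.94), (0.94, 0.66);
  healthy (0.81, 0.46), (0.88, 0.31).

Markers are drawn independently given disease status — the paper reports no
joint distribution, and conditional independence is what the serial-testing
arithmetic assumes. A Gaussian-copula correlation (default 0) is exposed for
sensitivity analysis; it changes the joint law but leaves the calibrated
marginals intact. Disease status is i.i.d. Bernoulli(π) by default; a
`fixed_counts` flag forces exactly round(n·π) cases for table reproduction.
One 64-bit seed drives three deterministic child streams (status, diseased
markers, healthy markers), so a cohort is a pure function of (spec,
prevalence).

What the generator does *not* emulate: raw e-nose sensor responses, urine
chemistry, demographic covariates (age/sex/BMI/smoking), or any
marker–covariate dependence. Passing tests on synthetic cohorts therefore
demonstrate that the *pipeline* recovers the operating points it was
calibrated to — not that the distributional families describe real patients
beyond those anchors. The two-decimal published rates (e.g. VOC sensitivity
"0.94" over 68 subjects, which cannot be an exact count ratio) are treated
as exact calibration targets; at n = 10⁵ the empirical rates recover them
within 3 binomial standard errors.

For exact reproduction of the FIT accuracy table, a separate deterministic
**rank-matched cohort** places 255 marker values in the inter-cutoff bins
the printed TP/TN counts imply, so direct tallying returns every cell; its
VOC scores are mid-rank quantiles of the calibrated Beta models (realistic,
not count-exact).

## Cross-validation harness

Subjects are shuffled once with a seeded generator and split into k
near-equal folds (k = 3 by default, labelled A, B, C; simple randomisation,
matching the study's description — a stratified option exists and is also
the automatic fallback, with a warning, if simple randomisation leaves a
training split single-class). Each fold is scored by a model trained on the
other k−1; out-of-fold scores are pooled into a single ROC rather than
averaging per-fold curves, matching the reporting of one AUC for the whole
cohort. At k = n the harness reduces to leave-one-out exactly.

The scorer is injectable (anything with `fit` and
`predict_proba`/`decision_function`); the default is logistic regression, a
stand-in for the study's neural-network classifier, whose architecture,
features and weights are unpublished — the harness and evaluation, not the
learner, are the point. A pass-through scorer reproduces the raw-score ROC
exactly, which the tests use as an identity check. Threshold selection:
`youden` maximises Se − (1−Sp) (ties toward higher specificity, then higher
threshold); `target_sensitivity` picks the most specific threshold whose
sensitivity still meets the target (on the published five-row score table,
targeting 0.94 selects 0.88) and raises, naming the maximum attainable, if
the target is unreachable.

`ScoreThresholdClassifier` wraps the harness as a scikit-learn estimator:
`fit` picks `threshold_` from the pooled out-of-fold ROC, then refits the
scorer on all training data; `predict` is `score ≥ threshold_`.

## Numerical and scale choices

- Monte-Carlo checks use 10⁵-subject cohorts: binomial SE ≈ 0.003 at the
  diseased-class size, small enough to separate calibration error from noise
  while generation stays around a second.
- The leave-one-out oracle comparison runs at n = 30; the Fagan/expected-count
  identity grid at 100 (Se, Sp, π) points.
- Degenerate inputs: empty cohorts and non-increasing threshold lists are
  rejected; zero-denominator metrics become `None` with a warning rather than
  poisoning a sweep; Sp ∈ {0, 1} makes a likelihood ratio undefined and
  raises with an explicit message; π ∈ {0, 1} are fixed points of the odds
  update; zero prevalence makes NNS undefined and raises.

## Known limitations

- The published VOC AUC (0.74) and combined-model AUC (0.61) depend on
  unpublished raw sensor data and network weights and are not reproduction
  targets; the synthetic-score AUC is whatever the calibrated Beta models
  imply.
- Published confidence intervals are internally inconsistent between the
  abstract and the accuracy table at the same cutoff, so no interval method
  can match both; intervals are reported but never asserted against printed
  values.
- The log-normal FIT model is a modelling stand-in constrained by two
  quantiles and a qualitative skew check, not an empirical fit to raw data.
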