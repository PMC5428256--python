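# Methods

## Model

Each patient's bladder volume after voiding is assumed to grow linearly,
`BV(t) = BV_residual + v_tot * t`, with a constant per-patient mean urinary
inflow rate `v_tot` (ml/min).  Across patients the rate is modelled as a
linear superposition of covariate effects

    v_tot = v0 + k_age * P_age + k_wat * P_wat + k_bmi * P_bmi,

with `v0` the net urinary inflow rate (ml/min), `P_age` age in years,
`P_wat` pre-session water intake in ml and `P_bmi` body-mass index in kg/m².
The covariates are treated as independent and their effects as additive; no
interactions, no regularization, and a single rate per patient (no
within-patient drift across treatment weeks).  The BMI effect is empirically
negligible, so the two-covariate model (`k_bmi = 0`) is the default.

All volumes are ml, times are minutes, rates ml/min.  The time origin is
**minutes since bladder voiding** throughout — voiding is the only physically
unambiguous zero, whereas "after drinking" depends on compliance.

## Per-patient estimation

`fit_inflow_plain` minimises `sum(((V_i - a - v*t_i)/sigma_v_i)^2)` by the
closed-form weighted normal equations; the slope standard error is taken
from the inverse weighted normal matrix (chi-square convention, no residual
rescaling), `ndf = n - 2`, and the fit probability is the chi-square
survival function computed as the regularized upper incomplete gamma
function `Q(ndf/2, chi2/2)`.

`fit_inflow_tu` incorporates a scan-time uncertainty `sigma_t` by the
standard effective-variance device: `sigma_eff_i^2 = sigma_v_i^2 +
(v*sigma_t_i)^2`, iterated until the slope changes by < 1e-6 ml/min (at most
50 iterations).  This is the natural chi-square treatment of an
errors-in-variables straight line; it reproduces the expected behaviour — a
compatible slope with an enlarged standard error — and reduces exactly to
the plain fit when `sigma_t = 0`.  The intercept is free, not pinned to the
residual urine, since the first scan need not occur at `t = 0`.

When a measurement carries no `sigma_v`, the fit substitutes
`0.05 * volume` (the generator's default measurement CV); a trajectory with
no usable sigma at all falls back to unit weights, which changes neither the
line nor the zero chi-square of noiseless fixtures.

`deviation_stats` summarises the relative residuals `(V_i - a - v*t_i)/V_0`
and tests their Gaussianity with a chi-square over `ceil(sqrt(n))`
equal-probability bins against the Gaussian with the sample mean and sd,
`ndf = bins - 3` (two estimated parameters plus normalisation).  The binning
rule is a documented choice; with fewer than four bins the probability is
reported as undefined rather than misleading.

## Population fits

**Regression.**  Ordinary least squares of the per-patient slope estimates
on the covariates with intercept (statsmodels under the hood), unbiased
residual-variance SEs, two-sided t p-values with `n - p` dof.
`regression3` includes BMI; `regression2` drops it.

**Iterative alternating fit.**  BMI is fixed to zero.  Initialisation: find
the largest subgroup of patients sharing one water value (within such a
subgroup the water term is constant, so regressing rate on age gives a clean
starting `k_age`); ties in subgroup size break toward the larger age spread.
Arbitrary cohorts may lack exact water ties, so a documented fallback bins
water to the nearest 50 ml for subgroup formation only.  Each pass then
alternates two component fits:

1. water fit: `vtot_hat - k_age*age` against water (free intercept) gives
   `v0` and `k_wat`;
2. age fit: `vtot_hat - v0 - k_wat*water` against age gives the next
   `k_age`.  The age fit's intercept is deliberately left free and is
   absorbed into `v0` by the next water fit (a `age_fit_intercept="zero"`
   switch forces it through the origin instead).

Passes repeat until both coefficient changes are below 0.01 (absolute, in
each coefficient's own units); a final water refit makes `v0`/`k_wat`
consistent with the converged `k_age`.  This alternation is Gauss–Seidel on
the OLS normal equations, so with weakly correlated covariates its fixed
point is the OLS solution and convergence is geometric — which is why the
two methods agree within one combined standard error on every synthetic
cohort, and why a paired t-test of their per-patient predictions is
non-significant (both fits match the sample mean exactly, so the mean
prediction difference is zero by construction).  Standard errors for the
iterative method are reported from the final-pass component fits; this
estimator is method-dependent and is labelled as such.

**Prediction** is the linear evaluation clamped below at 0.05 ml/min (the
physiological floor; e.g. the alternating-fit model at age 75 and 60 ml of
water evaluates to 0.007 ml/min and is clamped).  Predictions outside the
training covariate ranges warn.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| age | U(40, 75) yr | observed range; mean/median near 55 |
| water | U(60, 600) ml | observed range; mean near 320 |
| BMI | U(17.6, 28.2) kg/m² | observed range |
| truth coefficients | (3.115, −0.047, 0.007, 0) | final two-covariate model |
| patient scatter | 0.5 ml/min | spreads rates over ≈ 0.2–5 ml/min, the observed inter-patient span |
| measurement CV | 0.05 | portable-scanner error scales with volume; the per-scan CV is not published, so this is a documented assumption |
| time jitter | ±2.18 min | the stated maximum timing uncertainty from repeated sub-scans |
| residual urine | U(0, 30) ml | post-void residuals are evaluated clinically but unpublished; typical values are tens of ml |
| planning BV | U(150, 450) ml | typical planning volumes |

Covariates are uniform over the ranges because only means/medians/ranges are
reported, not distributions; a truncated-normal alternative (sd = range/4)
is config-exposed.  Latent rates below 0.05 ml/min are truncated to the
floor.  Recorded volumes carry multiplicative Gaussian noise floored at 0;
recorded times carry uniform jitter, floored at 0 and re-sorted.  Stored
per-point sigmas are derived from the latent (noise-free) volume — weighting
by the noisy volume itself would correlate weights with noise and bias
slopes low.

What the generator does **not** emulate: diurnal variation, diuretics,
within-course drift of bladder capacity, operator effects, non-linear
filling near capacity.  Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions, not robustness to these
real-data features.

## Validation

The measured rate is the test patient's fitted slope; the model deviation is
`(predicted - measured)/measured` (the measurement is the physical
reference; the denominator is switchable).  A patient is *consistent* when
the absolute deviation is within the tolerance, default 0.42.  That number
is derived from the per-method deviation statistics by the rule
`max over methods of (|mean| + sd)` — with (0.07 ± 0.34) and (−0.02 ± 0.40)
this yields 0.42.  The combination rule is an explicit, named, overridable
reading; only the resulting tolerance is externally given.  Nonphysical
(non-positive) measured rates are excluded from the consistency denominator
but counted and reported.  The net rate `v0` is separately checked from two
pre-drinking scans as `(BV(10) - BV(0))/10`; in the synthetic net-rate study
the pre-drinking filling rate is modelled as `v0` plus patient scatter,
matching how the clinical comparison interprets it.

## Scheduling

The first scan is taken at the predicted fill time
`(v_plan - residual)/v_tot_pred`.  A scan within ±15% of the planning volume
triggers treatment.  Otherwise the scan-implied rate
`(BV - residual)/t` replaces the model rate (their difference is the
*correction factor*) and:

- **underfull** → wait `(v_plan - BV)/v_tot_new`, rounded up to whole
  minutes and never less than the 10-min re-scan interval, then re-scan;
- **overfull** → void and restart the clock with the corrected rate (the
  protocol leaves void-vs-wait open; voiding is the default because waiting
  cannot empty a bladder, and a switch accepts overfilling up to twice the
  tolerance for sensitivity analysis).

Each measurement consumes 1 min of elapsed time (a full portable-ultrasound
measurement takes about a minute) but does not count as waiting; `wait_min`
accumulates all waiting after the first scan, i.e. overhead beyond the
predicted treat time.  Sessions abort after 6 scans.  Cohort summaries
report the one-scan / ≤3-scan / ≤5-scan fractions and scan-count and
wait-time histograms (12-min bins).

## Problem sizes and numerical choices

Recovery experiments use 200 patients per cohort, 7 scans at 10-min spacing
and 20 seeds, which gives coefficient means stable to well under the
acceptance tolerances while keeping a full run in seconds.  Sub-streams for
each pipeline stage derive from one master seed via `SeedSequence` spawn
keys, so stages can be re-run independently and identical configs give
byte-identical output bundles (CSV floats fixed at 6 decimals).  Degenerate
designs (constant covariates, identical scan times, zero-variance paired
differences) raise typed errors rather than returning NaNs.

## Known limitations

- The iterative method's standard-error estimator (final-pass component
  fits) understates the intercept uncertainty relative to the full OLS
  covariance, because each component fit conditions on the other
  coefficients.
- The workflow percentages of a real clinic (one-scan fractions, wait-time
  histogram shape) depend on unpublished per-patient data and protocol
  details; the scheduler reproduces the mechanism and its qualitative
  behaviour, and the simulated percentages should be read as such.
- The chi-square Gaussianity test with estimated parameters is approximate
  at small n; its null distribution is only asymptotically uniform.
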