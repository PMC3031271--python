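# Methods

## Model

The package models the probability of ventricular fibrillation (VF) after
an acute coronary event as an allometric function of the ECG ST-segment
deviation.  Writing `ΔST` for the unsigned deviation in mm (standard
calibration, 10 mm = 1 mV) and `P` for the event probability in percent,

    P = α (γ · ΔST)^β,        log P = δ + β · log ΔST,
    δ = log α + β · log γ.

`β` is the allometric exponent; `δ` is the intercept of the log-log line
and equals the log probability at 1 mm.  The mechanistic reading is that
`γ·ΔST` proxies the number of diseased ventricular fibers and `α(·)^β`
converts fiber count into event probability; only the composite `(β, δ)`
is ever identifiable from curve data, which is why the components appear
solely in `components_to_coefficients`.

Assumptions inherited from the data the model describes:

* event rates are plain proportions at a fixed horizon (no censoring or
  hazard structure — each follow-up window gets its own curve);
* depression and elevation are not distinguished: the deviation enters as
  a magnitude;
* the law is taken on the 0.5–2.0 mm window where the source cohorts
  report bins; outside it the power law extrapolates freely, so predicted
  "probabilities" above 100% are possible and are reported with a warning
  rather than clamped — the warning is the honest statement that the model
  has left its calibrated range.

### Logarithm base

The model's algebra is base-agnostic, and `β` is base-invariant (only `δ`
rescales, `δ_e = δ_10 · ln 10`).  Numerically, however, the published
coefficient table reproduces every quoted percentage **only** under
base-10 logarithms with probability on the 0–100 percent scale, so base 10
is the package default everywhere; base e is available through
`log_base="e"` and `convert_log_base`.  The `reproduce-paper --log-base e`
run documents the identification: under natural logs every equality-type
prediction misses its printed value (the single "below 11%" bound still
holds trivially, since base-e evaluation of base-10 coefficients only
shrinks the prediction).

## Fitting pipeline

Study curves arrive as 3–4 `(ΔST, P)` points.  The pipeline is:

1. **Quadratic resampling** onto a regular grid, default 0.5–2.0 mm in
   steps of 0.025 mm (61 points, endpoints inclusive; the point count is
   `round((high−low)/step)+1` so no floating accumulation).  "Quadratic
   interpolation" is implemented as a *local* second-order polynomial: each
   grid value comes from the parabola through the three input knots nearest
   to it (stable ties toward lower ST), solved directly as a 3×3
   Vandermonde system.  With exactly three input points — the typical bin
   structure — this is the unique interpolating parabola.  A C1 quadratic
   spline would be a different interpolant; the local form was chosen
   because the three-bin sources determine a single parabola anyway and the
   local rule extends it naturally to more knots.  No extrapolation is
   permitted: the requested window must lie inside the data span.
2. **Log-log OLS** of log(P) on log(ΔST) over the (resampled) points;
   slope is `β`, intercept is `δ`.  Goodness of fit is the two-parameter
   adjusted r², `1 − (1 − r²)(n − 1)/(n − 2)`.  r² is computed from
   residual and total sums of squares, so a perfectly fitted flat line
   (constant P) scores 1 instead of the 0/0 of the correlation form;
   a y-variance at float-noise level (≤ ~1e-24 relative) is treated as
   exactly constant.  Zero probabilities are rejected, not
   offset-corrected — no continuity correction is applied anywhere.

Resampling before fitting is the default because it mirrors how the
published coefficients were obtained; it is switchable (`resample=False`)
because on data that already follow an exact power law the parabola
through three bins is *not* an exact power law, so resample-then-fit
recovers the generating exponent only to ~0.01–0.02 while the direct fit
is exact.  Both behaviours are tested.

## Aggregation conventions

Two deliberately different conventions coexist, because the published
summaries themselves use two:

* **Probability-space mean + refit** (`mean_curve_refit`): evaluate each
  curve on the grid, take the pointwise arithmetic mean, band it with half
  the across-curve sample SD, and refit the law to the mean curve by
  log-log OLS on the grid (no further resampling).  This is the only
  convention that reproduces the published "mean" coefficient rows from
  the study-level rows.
* **Log10-space mean ± SEM** (`overall_average_band`): pointwise mean `m`
  and SEM `s` (sample SD over the n curves, divided by √n) of the log10
  values; centre `10^m` (the geometric mean, itself an exact power law
  with exponent equal to the mean of the input exponents), band
  `[10^(m−s), 10^(m+s)]`, which is multiplicatively symmetric.  This is
  the only convention that reproduces the published 17–32% prediction band
  at 1.5 mm.

The arithmetic/geometric inconsistency between the two summaries is
documented rather than harmonised.  SD always uses the n−1 divisor with n
the number of curves.

One published quantity resists exact recomputation: the 6-month mean-row
intercept prints as 1.16 while the probability-space refit gives 1.1657
(rounding to 1.17).  The slope (0.49) and the whole 1-month row (0.50,
1.01) reproduce exactly at two decimals, so the recomputation surface
carries the three derivable coefficients and the tests assert the 6-month
intercept only to ±0.01.  The study-level rows and the overall
"average curve" row (0.46, 1.28) are not recomputable at all — the per-bin
event rates they were fitted to were never published — and enter the
package purely as packaged constants.

## Synthetic data generator

`synthdata` emulates the *statistical structure* of the clinical
event-rate tables the fits consume, so the whole pipeline is testable
without the unpublished raw data:

* **ST bins** default to {0.5, 1.0, 2.0} mm, the sources'
  subclassification, with the open "≥ 2 mm" bin represented by its nominal
  2 mm value exactly as the fits treat it.
* **Follow-up windows** default to {1, 6, 12, 48} months, each with its
  own ground-truth law; the default truth is the published family (the two
  derived mean curves at 1 and 6 months, the long-horizon curves at 12 and
  48 months).
* **Noise** is binomial by default — observed probability `100·k/n` with
  `k ~ Binomial(n, p)` — because the source trials report event
  proportions among cohorts of stated sizes.  The default cohort size of
  2 000 patients per bin is the largest source cohort (~6 300 evaluated
  patients) split evenly across the three bins; the true per-bin split was
  never published, so the even split is a synthetic convention.  A
  lognormal model (Gaussian noise on log10 P, configurable SD, clipped at
  100%) is provided for regression-theory tests; σ = 0 gives exact curves.
* **Zero-event bins** (possible at small cohorts where p ≈ 5%) are redrawn
  once and, if still zero, dropped with a warning — their log does not
  exist, and no continuity correction is introduced.
* **Determinism**: one seed fixes the full output; replicate seeds in
  `recovery_experiment` are spawned from the config seed via
  `SeedSequence`, and failed replicates (e.g. a dropped bin leaving too
  few points) are counted separately rather than silently ignored.

What passing synthetic tests shows — and does not.  They show the
estimator is consistent and nearly unbiased under binomial sampling around
a true power law (bias of β̂ below 0.02 at 10 000 patients/bin, RMSE
decreasing with cohort size).  They do not validate the allometric form
against real patients: real ST-bin event rates include measurement
conventions (caliper reading, J-point offsets, bin rounding) and cohort
heterogeneity that the generator does not emulate.

## Numerical and design choices

* Reporting precision mirrors the published tables — coefficients to 2
  decimals, probabilities to integer percent — applied only at the
  CLI/report layer; all internal computation is full double precision.
* The OLS itself is `scipy.stats.linregress`; the test suite checks it
  against an independent explicit normal-equations solve to 1e-10 on
  random inputs, so the regression backend is replaceable.
* Simulation sizes in the default test run (≤ 200 replicates, cohorts up
  to 10 000) keep the whole suite in a few seconds while leaving the
  binomial moment checks well inside 3-SE bands.
* The CLI is a thin layer: every subcommand calls one library function,
  results go to stdout, diagnostics to stderr, exit codes 0/2/3
  (success / validation error / strict reproduction mismatch).

## Known limitations

* Fixed-horizon proportions only: no censoring, no patient-level
  covariates, no confidence intervals on `(β, δ)` beyond the empirical
  spread the recovery experiment reports.
* The 0.5–2.0 mm window is where the model is calibrated; predictions
  outside it are extrapolations and are flagged, not forbidden.
* The two aggregation conventions answer different questions (average
  curve vs typical log-scale curve); neither is "the" average, and mixing
  them changes second-decimal coefficients.
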