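# Methods

## The forecasting problem

A daily count series of outpatient blood collections is forecast one week
ahead. The series is non-stationary, with four features that drive every
design choice here: a strong day-of-week profile (Monday elevated, volume
declining through the week, Saturday low, Sunday far lower), an annual
seasonal swing, a slow trend, and holiday days whose volume collapses
toward weekend levels. Counts are large (thousands per weekday), so they
are treated as continuous for modelling and rounded only for display.

All weekly structure runs Monday-first; weeks are indexed 1-based from the
first trimmed Monday of the input, and emitted reports carry calendar
dates rather than week numbers so results stay unambiguous across sources
that number weeks differently.

## Preprocessing

The series is first trimmed to whole Monday–Sunday weeks (incomplete
cycles would break the week × weekday panel). Outliers are screened per
weekday column of that panel: a cell is flagged when it lies more than
`sd_multiple` (default 2) sample standard deviations (denominator n−1 —
the number of weeks per column is small) from its column mean. Detection
is a single pass with thresholds from the original columns; thresholds are
not re-derived as cells are replaced, so the flag set is a fixed property
of the input.

"Neighbouring period" replacement is read as the same weekday in the
adjacent earlier and adjacent later week (the series' period is the week);
each flagged cell becomes the mean of the nearest non-flagged week on each
side, falling back to the two nearest clean weeks on one side at the panel
boundary. A `preceding` mode (two earlier weeks) is available for users
who prefer strictly causal imputation.

## The differenced moving-average model

Default differencing is one regular plus one lag-7 seasonal pass
(d = 1, D = 1, s = 7): the described operation — a first-order seven-step
difference — and the weekly periodicity both demand the seasonal pass, and
"order 2" is read as the total number of differencing passes. A pure
d = 2 regular mode is selectable in the config for users who want two
regular passes instead.

The differenced series is modelled as a pure moving average with no
intercept (differencing removes the level) and no autoregressive part.
Sign convention: `Θ(B) = 1 − θ₁B − … − θ_qB^q`, matching the sign of
coefficient estimates printed by standard statistical software.

Estimation is conditional least squares: pre-sample innovations are fixed
at zero, the innovation recursion is evaluated as a linear filter, and the
sum of squared innovations is minimised by BFGS from a white-noise start.
Invertibility is enforced structurally by optimising over partial
coefficients squashed through tanh and mapped to MA coefficients by a
Levinson-type recursion, so every iterate (and therefore every returned
fit) has `Θ(B)` roots outside the unit circle. `σ̂² = SSE/n`,
`BIC = n ln σ̂² + (q+1) ln n` with n the post-differencing sample size and
q+1 counting the coefficients plus the innovation variance. Standard
errors come from a central-difference Hessian of the SSE in coefficient
space (`cov ≈ σ̂² (H/2)⁻¹`). A failed optimisation raises with the
optimiser's diagnostics; no silent fits. (BFGS termination with
"precision loss" at an already-stationary point is accepted — it reports
the same minimiser.)

Order selection minimises BIC over a candidate set, breaking ties toward
the smaller order. Residual adequacy uses the Ljung-Box statistic
`Q = n(n+2) Σ r_k²/(n−k)` with df = lag − q floored at zero; df-0 rows
carry no p-value. Stationarity checking is informational (correlogram
inspection); the differencing spec is user-set because order choice by
visual identification cannot be automated faithfully. An optional log
transformation of the counts is available but off by default — the
pipeline's standard path applies differencing only.

Forecasts set future innovations to zero (so differenced-scale forecasts
vanish beyond lag q) and invert the differencing exactly by the backshift
polynomial recursion. The horizon is capped at 7 days, the window this
pipeline is designed and validated for.

## Per-weekday exponential smoothing

One smoother per weekday across weeks. The smoothed value at week t' is
the one-step-ahead forecast of week t'; the recursion is initialised with
the mean of the first three weeks' observations. The smoothing constant
is selected per weekday by exhaustive grid search over 0.001…0.999 in
steps of 0.001 — the grid must resolve three decimals because optimal
constants for very stable weekdays are of order 10⁻³. The selection
objective is the one-step MSE accumulated from week 4 onward, so the
initialisation window does not dominate the objective (the accumulation
range was an open choice; post-initialisation is this package's
decision). MAPE is reported alongside and can be made the objective. The
open interval constraint on α is realised by the grid endpoints.

## Forecast combination

"Residual correction" is operationalised as constrained least squares on
the two models' aligned historical one-step residuals: minimise
`Σ (w₁e₁ + w₂e₂)²` subject to `w₁ + w₂ = 1` (a closed-form 1-D
quadratic), then clip to [0, 1] and renormalise so the combination stays
convex — extrapolative weights are deliberately excluded. Inverse-error
weighting and the Bates–Granger variance-minimising rule are selectable
alternatives; all three are standard residual-based combiners.

For the ARIMA model the one-step-ahead error on the count scale equals
the innovation ε_t (differencing is linear in known past values), so the
in-sample innovations serve as its residual series. Both residual series
are restricted to whole weeks from week 4 of the fitting window onward —
after the smoother's three-week initialisation and the 8-day differencing
burn-in — and weights are re-estimated at every rolling origin. Which
residual window feeds the estimator was an open choice; in-sample
residuals over the full post-burn-in fitting window are the default, and
a sub-window can be passed explicitly.

## Evaluation

MAPE over strictly positive observed counts; a zero observation is an
error rather than a silently skipped term. A weekly report carries the 7
per-day absolute percentage errors with overall (mean of 7), workday
(mean of Mon–Fri) and weekend (mean of Sat–Sun) summaries — all
unweighted arithmetic means of per-day APEs, computed unrounded and
rounded to 2 decimals only for display. Rolling evaluation forecasts each
test week from data through the preceding week only, refitting all three
models and the weights at each origin; pooled summaries average per-day
APEs across test weeks with equal week weights.

## Synthetic generator

The generator emulates the documented structure of a real sampling-room
series: mean function
`(base + slope·t) · profile[τ] · (1 + A·sin(2πt/364))`, additive Gaussian
noise, independent Bernoulli holiday days scaled by a factor in [0, 1],
clipped at zero and rounded. The 364-day (52-week) annual cycle keeps
annual and weekly periods commensurate so whole-week trimming never cuts
the annual cycle mid-phase. Holidays as i.i.d. Bernoulli days with a
multiplicative depression are the simplest mechanism that produces 2-SD
outliers; no real holiday calendar is used.

Defaults are calibrated so a 61-week run reproduces the reference
magnitude — sample mean ≈ 3952.6, SD ≈ 1702.36 — with the weekday profile
(1.363, 1.305, 1.289, 1.231, 1.013, 0.608, 0.191; mean 1) shaped to the
documented weekly pattern, base level 3799, trend 0.9 counts/day, annual
amplitude 0.11, noise SD 140, holiday rate 0.03 and holiday factor 0.45.
The profile values are synthetic package defaults, not measurements. What
the generator does **not** emulate: calendar-locked holidays (and their
clustering around the lunar new year), day-of-week-dependent noise,
gradual regime changes, or recording artefacts. Tests passing on this
synthetic family therefore demonstrate correctness of the algorithms and
robustness to the stated structure, not performance on any particular
hospital's data.

The outlier-injection helper places each injected value beyond
`magnitude` leave-one-out SDs of its weekday column and escalates the
offset until the perturbed column's own statistics also flag it. A hard
limit of sample statistics applies: a single point among n weeks can sit
at most `(n−1)/√n` sample SDs from the column mean, so self-consistent
placement at 3 SDs needs ≥ 11 weeks; below that the leave-one-out
guarantee still holds.

## Numerical and degenerate-input choices

- Differencing inversion is exact (backshift polynomial recursion), so
  forecast errors are purely model errors, never reconstruction errors.
- Constant series: autocorrelations are undefined and returned as NaN.
- Identical residual series in weight estimation: flat objective, returns
  (0.5, 0.5) with a warning.
- Flat α-selection objective: tie-break toward the smallest grid value.
- BIC ties: smaller order wins.
- All simulation-based defaults and tests derive their randomness from
  explicit integer seeds; identical config + seed gives bit-identical
  output end to end.

## Problem sizes

The bundled evaluation and the acceptance script use 61-week synthetic
series (52 fitting weeks + 8 rolling test weeks after the one-week offset
of the plan), 10 seeded replicates for the rolling summaries and 8 for
the calibration check; parameter-recovery checks use series of length
500–2000 with up to 50 seeded replicates. These sizes give stable
Monte-Carlo estimates (a few percent relative error) while keeping a full
run in seconds.

## Known limitations

- The workday summary is the arithmetic mean of Mon–Fri APEs; published
  workday figures for the bundled reference week follow a formula that
  matches neither the mean nor the sum of the printed per-day values, so
  that column is reported under this package's definition and will differ
  from the published cells (the weekend column reconciles exactly).
- The combination cannot help when both models share the same error sign
  and magnitude (e.g. both miss a holiday); weights fix relative
  emphasis, not common bias.
- Ljung-Box p-values on real-scale synthetic runs can be small because
  the annual cycle is not part of the MA model; the pipeline follows the
  standard practice of treating high p-values at lags beyond q as the
  pass criterion while still reporting the full table.
- No prediction intervals; the pipeline reports point forecasts and MAPE
  only.
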