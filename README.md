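# bloodcast

Forecasting daily outpatient blood-collection demand one week ahead.

Outpatient blood-sampling rooms in large hospitals see several thousand
patients a day, with a strong day-of-week effect (Monday peak, deep Sunday
trough), annual seasonal swings, a gentle trend, and holiday-driven
outliers. Accurate week-ahead forecasts of the daily count let managers
schedule nursing staff before the week starts. `bloodcast` implements a
combined forecasting pipeline for such series, aimed at hospital
operations analysts and anyone forecasting strongly weekly-periodic daily
counts.

## The model

Let `Y_t` be the daily count, with `t = 7(t'-1) + τ` linking the daily
index to week `t'` and weekday `τ ∈ {1..7}` (Monday = 1). The pipeline
fits two complementary models and blends them:

1. **Seasonal-difference ARIMA.** One regular plus one lag-7 seasonal
   difference, `w_t = (1-B)(1-B⁷) Y_t`, removes trend and the weekly
   cycle; the remainder is modelled as a pure moving average
   `w_t = Θ(B) ε_t` with `Θ(B) = 1 - θ₁B - … - θ_qB^q`, fitted by
   conditional least squares, with order `q` chosen by BIC
   (`BIC = n ln σ̂² + (q+1) ln n`) and residuals screened by the
   Ljung-Box portmanteau test (df = lag − q). Forecasts set future
   innovations to zero and invert the differencing exactly, giving `Ŷ¹_t`.
2. **Per-weekday simple exponential smoothing.** For each weekday, the
   across-week recursion `Ŷ²_{t'+1,τ} = α y_{t',τ} + (1-α) Ŷ²_{t',τ}`,
   initialised with the mean of the first three weeks; each `α` is chosen
   by exhaustive grid search (step 0.001) minimising the one-step MSE.
3. **Residual-correction combination.**
   `Ŷ_{t',τ} = W₁ Ŷ¹_t + W₂ Ŷ²_{t',τ}` with `W₁ + W₂ = 1`, the weights
   estimated from the two models' historical one-step residuals by
   constrained least squares (inverse-error and Bates–Granger weighting
   are available as alternatives).

Before modelling, the series is trimmed to whole Monday–Sunday weeks and
"singularities" — days beyond 2 sample SDs of their weekday's mean — are
replaced by same-weekday neighbour averages. Accuracy is measured by
`MAPE = 100/N · Σ |Y_t − Ŷ_t| / Y_t` under a rolling protocol: each test
week is forecast using only data through the preceding week, with all
models re-estimated at every origin.

A seeded synthetic generator reproduces the statistical structure of a
real sampling-room series (long-run mean ≈ 3950, SD ≈ 1700, Monday ≈ 7×
Sunday), so the whole pipeline is testable without hospital data.

## Worked example

A published single-week case study (observed counts, both component
forecasts, and weights W₁ = 0.73, W₂ = 0.27) is bundled as an input
fixture:

```
$ bloodcast reproduce-week61
Model                Mon    Tue    Wed    Thu    Fri    Sat    Sun     Overall Workday Weekend
ARIMA model          0.93%  0.16%  0.08%  2.78%  0.77%  1.33%  17.22%  3.32%   0.94%   9.28%
SES model            0.19%  0.70%  0.49%  1.89%  2.12%  3.67%  16.95%  3.72%   1.08%  10.31%
Combinatorial model  0.73%  0.08%  0.08%  2.54%  0.01%  1.96%  17.15%  3.22%   0.68%   9.55%
Smoothing factor     0.099  0.200  0.006  0.100  0.003  0.027  0.199   /       /       /
```

Each cell is the absolute percentage error of that day's forecast; the
combined model's overall MAPE (3.22%) beats both components (3.32%,
3.72%). Sunday — the smallest, most volatile count — dominates the error
everywhere.

From Python, the full pipeline on synthetic data:

```python
from bloodcast import GeneratorConfig, PipelineConfig, generate_series, run_pipeline

series = generate_series(GeneratorConfig(n_weeks=61, seed=8))
result = run_pipeline(PipelineConfig(fit_weeks=[1, 53], test_weeks=[54, 61]), series)
for m, rep in result.rolling.pooled.items():
    print(m, f"{rep.overall_mape:.2f}%")
# arima 6.50%  /  ses 5.21%  /  combined 4.89%
```

The `examples/` directory has one short narrative script per capability
(simulation, outlier cleaning, each model, combination, rolling
evaluation); run them with `python examples/01_simulate.py` etc.

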