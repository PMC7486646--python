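"""Difference the series, fit the MA(7) model, diagnose, forecast 7 days.

One regular plus one lag-7 seasonal difference removes trend and the weekly
cycle; the stationary remainder is fitted by conditional least squares, the
residuals are screened with the Ljung-Box portmanteau test (degrees of
freedom reduced by the 7 fitted coefficients), and the forecast is mapped
back to counts by exact difference inversion.
"""

from bloodcast import (DifferenceSpec, GeneratorConfig, difference,
                       fit_ma, forecast_arima, generate_series, ljung_box,
                       mape)

series = generate_series(GeneratorConfig(n_weeks=61, seed=2))
train = type(series)(series.dates[:-7], series.counts[:-7])

spec = DifferenceSpec(d=1, D=1, s=7)
w = difference(train.counts, spec)
fit = fit_ma(w, q=7)

print(f"MA(7) by conditional least squares: BIC {fit.bic:.1f}, "
      f"sigma^2 {fit.sigma2:.0f}")
for i, (th, t) in enumerate(zip(fit.theta, fit.t_values), 1):
    print(f"  theta_{i} = {th:+.4f}  (t = {t:+.1f})")

print("lag   Q      df  p")
for r in ljung_box(fit.residuals, [6, 12, 18, 24, 30], n_fitted_params=7):
    p = "-" if r.p_value is None else f"{r.p_value:.4f}"
    print(f"{r.lag:3d} {r.q_stat:7.2f} {r.df:3d}  {p}")

fc = forecast_arima(train, spec, fit, horizon=7)
print("forecast:", " ".join(f"{v:7.0f}" for v in fc))
print("observed:", " ".join(f"{v:7.0f}" for v in series.counts[-7:]))
print(f"7-day MAPE {mape(series.counts[-7:], fc):.2f}% — the error of the "
      "week-ahead forecast on the held-out final week.")
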