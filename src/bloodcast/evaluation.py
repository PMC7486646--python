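"""MAPE scoring, weekly reports, and rolling-origin evaluation.

Accuracy is measured by the mean absolute percentage error

    MAPE = 100/N * sum_t |Y_t - Y_hat_t| / Y_t,

the natural scale-free metric for strictly positive daily counts.  A weekly
report breaks the seven APEs down into overall (mean of all 7), workday
(mean of Mon-Fri) and weekend (mean of Sat-Sun) summaries.

The rolling-origin protocol mirrors operational use: a block of fitting
weeks, then each test week forecast one week ahead using only data through
the preceding week, with every model — the differenced moving-average
model, the seven weekday smoothers, and the combination weights —
re-estimated at each origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arima import DifferenceSpec, difference, fit_ma, forecast_arima
from .combine import CombinationWeights, combine, estimate_weights
from .series import DailyCountSeries, WeekdayPanel, to_panel
from .ses import forecast_ses

__all__ = ["mape", "EvalReport", "week_report", "RollingPlan",
           "rolling_evaluate", "RollingResult"]


def mape(observed, predicted) -> float:
    """Mean absolute percentage error, as a percentage.

    All observed values must be strictly positive (daily collection counts
    are); a zero observation would make the metric undefined.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if np.any(y <= 0):
        raise ValueError("MAPE undefined: observed values must be > 0")
    return float(100.0 * np.mean(np.abs(y - yhat) / y))


@dataclass(frozen=True)
class EvalReport:
    """Per-day APEs of one forecast week with Mon-Sun summaries.

    ``overall_mape`` is the unweighted mean of the 7 per-day APEs;
    ``workday_mape`` averages Mon-Fri and ``weekend_mape`` Sat-Sun.
    ``residuals`` are signed count errors (observed - predicted).
    """

    per_day_ape: np.ndarray
    overall_mape: float
    workday_mape: float
    weekend_mape: float
    residuals: np.ndarray
    n: int = 7


def week_report(observed_week, predicted_week) -> EvalReport:
    """Score one Monday-first forecast week of exactly 7 days."""
    y = np.asarray(observed_week, dtype=float)
    yhat = np.asarray(predicted_week, dtype=float)
    if y.shape != (7,) or yhat.shape != (7,):
        raise ValueError("week_report expects exactly 7 aligned values")
    if np.any(y <= 0):
        raise ValueError("observed counts must be > 0")
    ape = 100.0 * np.abs(y - yhat) / y
    return EvalReport(per_day_ape=ape,
                      overall_mape=float(ape.mean()),
                      workday_mape=float(ape[:5].mean()),
                      weekend_mape=float(ape[5:].mean()),
                      residuals=y - yhat)


@dataclass(frozen=True)
class RollingPlan:
    """Inclusive 1-based week ranges for fitting and testing.

    The test range must start right after the fit range; each test week is
    forecast from data through the preceding week only, refitting all
    models at every origin.
    """

    fit_weeks: tuple[int, int]
    test_weeks: tuple[int, int]
    refit: bool = True

    def __post_init__(self) -> None:
        f0, f1 = self.fit_weeks
        t0, t1 = self.test_weeks
        if not (1 <= f0 <= f1):
            raise ValueError(f"invalid fit range {self.fit_weeks}")
        if t0 != f1 + 1 or t1 < t0:
            raise ValueError(f"test range {self.test_weeks} must follow fit "
                             f"range {self.fit_weeks} with no gap")


@dataclass(frozen=True)
class RollingResult:
    """Per-week and pooled scores for the three models."""

    weekly: dict            # model -> list[EvalReport], one per test week
    pooled: dict            # model -> EvalReport-like pooled summary
    weights: list           # CombinationWeights per origin
    forecasts: dict         # model -> (n_test_weeks, 7) forecast matrix
    observed: np.ndarray    # (n_test_weeks, 7) observed matrix


def _pool(reports: list[EvalReport]) -> EvalReport:
    """Average per-day APEs across test weeks (equal week weights)."""
    ape = np.mean([r.per_day_ape for r in reports], axis=0)
    resid = np.mean([r.residuals for r in reports], axis=0)
    return EvalReport(per_day_ape=ape, overall_mape=float(ape.mean()),
                      workday_mape=float(ape[:5].mean()),
                      weekend_mape=float(ape[5:].mean()),
                      residuals=resid, n=7 * len(reports))


def _one_step_residual_panels(train: DailyCountSeries, spec: DifferenceSpec,
                              fit, ses_fits) -> tuple[np.ndarray, np.ndarray]:
    """Aligned level-scale one-step residual panels for weight estimation.

    For the differenced MA model the one-step-ahead level error equals the
    innovation eps_t (differencing is linear in known past values), defined
    from day burn_in + 1 onward; for the smoothers the one-step error is
    y_{t',tau} - S_{t',tau}.  Both are restricted to whole weeks after both
    models' burn-in: weeks 4 onward (the smoothers' three-week
    initialisation outlasts the 8-day differencing burn-in).
    """
    n = len(train)
    w_weeks = n // 7
    resid1 = np.full(n, np.nan)
    resid1[spec.burn_in:] = fit.residuals
    resid1_panel = resid1.reshape(w_weeks, 7)
    panel = to_panel(train)
    resid2_panel = np.empty((w_weeks, 7))
    for tau in range(1, 8):
        resid2_panel[:, tau - 1] = panel.column(tau) - ses_fits[tau - 1].smoothed
    start = max(3, int(np.ceil(spec.burn_in / 7)))
    return resid1_panel[start:].ravel(), resid2_panel[start:].ravel()


def rolling_evaluate(series: DailyCountSeries, plan: RollingPlan,
                     spec: DifferenceSpec = DifferenceSpec(),
                     q: int = 7, alphas="auto",
                     weight_method: str = "cls") -> RollingResult:
    """Run the one-week-ahead rolling evaluation of the three models.

    For each test week w the moving-average model, the seven weekday
    smoothers and the combination weights are re-estimated on weeks
    ``fit_weeks[0]..w-1`` and week w is forecast and scored.  Week w's data
    are never used in the models that forecast it.
    """
    panel = to_panel(series)
    t0, t1 = plan.test_weeks
    if t1 > panel.n_weeks:
        raise ValueError(f"test range ends at week {t1} but series has "
                         f"{panel.n_weeks} weeks")
    f0 = plan.fit_weeks[0]
    weekly = {"arima": [], "ses": [], "combined": []}
    weights_per_origin = []
    fc = {"arima": [], "ses": [], "combined": []}
    observed = []
    for w in range(t0, t1 + 1):
        # training data: weeks f0 .. w-1
        lo, hi = (f0 - 1) * 7, (w - 1) * 7
        train = DailyCountSeries(series.dates[lo:hi], series.counts[lo:hi])
        diff = difference(train.counts, spec)
        fit = fit_ma(diff, q)
        pred1 = forecast_arima(train, spec, fit, horizon=7)
        pred2, ses_fits = forecast_ses(to_panel(train), alphas)
        r1, r2 = _one_step_residual_panels(train, spec, fit, ses_fits)
        weights = estimate_weights(r1, r2, method=weight_method,
                                   window=(f0, w - 1))
        cf = combine(pred1, pred2, weights)
        obs = panel.values[w - 1]
        weekly["arima"].append(week_report(obs, pred1))
        weekly["ses"].append(week_report(obs, pred2))
        weekly["combined"].append(week_report(obs, cf.combined))
        weights_per_origin.append(weights)
        fc["arima"].append(pred1)
        fc["ses"].append(pred2)
        fc["combined"].append(cf.combined)
        observed.append(obs)
    pooled = {m: _pool(reps) for m, reps in weekly.items()}
    return RollingResult(weekly=weekly, pooled=pooled,
                         weights=weights_per_origin,
                         forecasts={m: np.array(v) for m, v in fc.items()},
                         observed=np.array(observed))
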