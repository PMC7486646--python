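"""Per-weekday simple exponential smoothing.

Daily demand has a strong day-of-week effect, so rather than smoothing the
daily series directly, one SES model is fitted to each weekday's sub-series
across weeks (Mondays across weeks, Tuesdays across weeks, ...).  For a
weekday tau with observations y_{t',tau} over weeks t', the smoothed value
S_{t'} acts as the one-step-ahead forecast of week t' and obeys

    S_{t'+1} = alpha * y_{t'} + (1 - alpha) * S_{t'},    0 < alpha < 1,

initialised with the mean of the first three weeks' observations.  The
smoothing constant is chosen per weekday by exhaustive grid search over
(0, 1) at 0.001 resolution, minimising the in-sample one-step mean squared
error accumulated after the three-week initialisation window (so the
initialisation itself does not dominate the objective); the corresponding
MAPE is reported alongside, and can be made the selection objective
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import WeekdayPanel

__all__ = ["SESFit", "init_level", "ses_smooth", "select_alpha",
           "forecast_ses", "DEFAULT_ALPHA_GRID"]

#: 0.001, 0.002, ..., 0.999 — resolves smoothing constants to 3 decimals.
DEFAULT_ALPHA_GRID = np.round(np.arange(1, 1000) / 1000.0, 3)

#: First in-sample week (0-based) whose one-step error enters the alpha
#: selection objective; weeks 1-3 form the initialisation window.
_SELECTION_START = 3


@dataclass(frozen=True)
class SESFit:
    """A fitted per-weekday smoothing model.

    ``smoothed[i]`` is the one-step-ahead forecast of week ``i+1`` (1-based),
    made from data through week ``i``; ``forecast_next`` extends the
    recursion one week past the sample.
    """

    weekday: int
    alpha: float
    initial_level: float
    smoothed: np.ndarray
    forecast_next: float
    in_sample_mse: float
    in_sample_mape: float


def init_level(weekday_series) -> float:
    """Initial smoothing level: the mean of the first three weeks."""
    y = np.asarray(weekday_series, dtype=float)
    if len(y) < 3:
        raise ValueError(f"need at least 3 observations to initialise, "
                         f"got {len(y)}")
    return float(y[:3].mean())


def ses_smooth(weekday_series, alpha: float, initial_level: float,
               weekday: int = 0) -> SESFit:
    """Run the smoothing recursion at a fixed alpha.

    One-step errors are y_{t'} - S_{t'}; the reported MSE/MAPE accumulate
    from week 4 onwards (after the initialisation window) when the series
    is long enough, else over all weeks.
    """
    y = np.asarray(weekday_series, dtype=float)
    if len(y) == 0:
        raise ValueError("weekday series is empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    smoothed = np.empty(len(y))
    smoothed[0] = initial_level
    for i in range(1, len(y)):
        smoothed[i] = alpha * y[i - 1] + (1 - alpha) * smoothed[i - 1]
    forecast_next = float(alpha * y[-1] + (1 - alpha) * smoothed[-1])
    start = _SELECTION_START if len(y) > _SELECTION_START else 0
    err = y[start:] - smoothed[start:]
    mse = float(np.mean(err ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        mape = float(100.0 * np.mean(np.abs(err) / y[start:]))
    return SESFit(weekday=weekday, alpha=float(alpha),
                  initial_level=float(initial_level), smoothed=smoothed,
                  forecast_next=forecast_next, in_sample_mse=mse,
                  in_sample_mape=mape)


def _grid_objective(y: np.ndarray, grid: np.ndarray, level0: float,
                    objective: str) -> np.ndarray:
    """Vectorised one-step-error objective over the whole alpha grid."""
    n = len(y)
    smoothed = np.empty((len(grid), n))
    smoothed[:, 0] = level0
    for i in range(1, n):
        smoothed[:, i] = grid * y[i - 1] + (1 - grid) * smoothed[:, i - 1]
    start = _SELECTION_START if n > _SELECTION_START else 0
    err = y[start:] - smoothed[:, start:]
    if objective == "mse":
        return np.mean(err ** 2, axis=1)
    if objective == "mape":
        return 100.0 * np.mean(np.abs(err) / y[start:], axis=1)
    raise ValueError(f"unknown objective {objective!r}")


def select_alpha(weekday_series, grid=DEFAULT_ALPHA_GRID,
                 objective: str = "mse") -> float:
    """Exhaustive grid search for the smoothing constant.

    Returns the grid value minimising the in-sample one-step error
    (MSE by default, MAPE optionally); ties break toward the smaller
    alpha, so a flat objective yields the smallest grid value.
    """
    y = np.asarray(weekday_series, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("alpha grid values must lie strictly in (0, 1)")
    order = np.argsort(grid, kind="stable")
    grid_sorted = grid[order]
    scores = _grid_objective(y, grid_sorted, init_level(y), objective)
    return float(grid_sorted[int(np.argmin(scores))])


def forecast_ses(panel: WeekdayPanel, alphas="auto",
                 grid=DEFAULT_ALPHA_GRID, objective: str = "mse"):
    """Fit all seven weekday smoothers and forecast the next week.

    ``alphas`` is either ``"auto"`` (per-weekday grid selection) or a
    sequence of 7 manual smoothing constants, Monday..Sunday.  Returns
    ``(forecasts, fits)``: the 7 next-week predictions and the per-weekday
    :class:`SESFit` objects.
    """
    if panel.n_weeks < 4:
        raise ValueError(f"need >= 4 weeks (3 to initialise + 1 to smooth), "
                         f"got {panel.n_weeks}")
    if isinstance(alphas, str):
        if alphas != "auto":
            raise ValueError(f"alphas must be 'auto' or 7 values, "
                             f"got {alphas!r}")
        chosen = None
    else:
        chosen = [float(a) for a in alphas]
        if len(chosen) != 7:
            raise ValueError(f"expected 7 manual alphas, got {len(chosen)}")
    fits = []
    for tau in range(1, 8):
        y = panel.column(tau)
        alpha = (select_alpha(y, grid, objective) if chosen is None
                 else chosen[tau - 1])
        fits.append(ses_smooth(y, alpha, init_level(y), weekday=tau))
    forecasts = np.array([f.forecast_next for f in fits])
    return forecasts, fits
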