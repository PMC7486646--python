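"""Synthetic daily blood-collection series.

Real outpatient blood-sampling counts show (i) a strong day-of-week profile —
a Monday peak, a mild decline through the working week, a low Saturday and a
far lower Sunday — (ii) a slow annual swing, (iii) a gentle trend, (iv)
day-to-day noise, and (v) occasional holiday days with sharply depressed
volume.  The generator produces series with exactly this structure, so the
whole pipeline can be exercised and tested without any hospital data.

The mean function of day (t', tau), with t = 7*(t'-1) + tau the daily index,
is

    mu(t) = (base_level + trend_slope * t) * profile[tau]
            * (1 + annual_amplitude * sin(2*pi*t / 364))

(a 364-day annual cycle keeps annual and weekly periods commensurate, so
whole-week trimming never cuts the annual cycle mid-phase).  Gaussian noise
is added, Bernoulli holiday days are scaled down by ``holiday_factor``, and
the result is clipped at zero and rounded to integer counts.

The default configuration is calibrated so a long run reproduces the
magnitude of a large Chinese general hospital's sampling room: a long-run
mean of about 3950 collections per day with a standard deviation around
1700, dominated by the weekday profile (Sunday running near 19% of the
weekly mean).  The profile values are synthetic package defaults shaped to
that qualitative pattern, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import DailyCountSeries, to_panel

__all__ = ["GeneratorConfig", "generate_series", "inject_singularities"]

#: Synthetic weekday multipliers, Monday..Sunday, mean exactly 1.
DEFAULT_WEEKDAY_PROFILE = (1.363, 1.305, 1.289, 1.231, 1.013, 0.608, 0.191)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic daily-count generator.

    Attributes
    ----------
    n_weeks
        Number of whole Monday-Sunday weeks to generate.
    base_level
        Mean weekday count at t = 0 (counts/day).
    weekday_profile
        Seven non-negative multipliers, Monday..Sunday.
    annual_amplitude
        Relative amplitude of the 364-day sinusoidal cycle (fraction of the
        local level, >= 0).
    trend_slope
        Linear drift in counts per day (may be negative).
    noise_sd
        Standard deviation of additive Gaussian noise (counts).
    holiday_rate
        Per-day probability of a holiday in [0, 1].
    holiday_factor
        Multiplier in [0, 1] applied to a holiday day's count.
    seed
        RNG seed; the same config and seed give a bit-identical series.
    """

    n_weeks: int = 61
    base_level: float = 3799.0
    weekday_profile: tuple = DEFAULT_WEEKDAY_PROFILE
    annual_amplitude: float = 0.11
    trend_slope: float = 0.9
    noise_sd: float = 140.0
    holiday_rate: float = 0.03
    holiday_factor: float = 0.45
    seed: int = 0
    start_date: str = "2018-03-05"  # a Monday

    def __post_init__(self) -> None:
        if int(self.n_weeks) <= 0:
            raise ValueError(f"n_weeks must be a positive integer, "
                             f"got {self.n_weeks}")
        profile = tuple(float(p) for p in self.weekday_profile)
        if len(profile) != 7:
            raise ValueError(f"weekday_profile must have exactly 7 entries, "
                             f"got {len(profile)}")
        if any(p < 0 for p in profile):
            raise ValueError("weekday_profile entries must be >= 0")
        if self.annual_amplitude < 0:
            raise ValueError("annual_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.holiday_rate <= 1.0:
            raise ValueError("holiday_rate must lie in [0, 1]")
        if not 0.0 <= self.holiday_factor <= 1.0:
            raise ValueError("holiday_factor must lie in [0, 1]")
        object.__setattr__(self, "weekday_profile", profile)

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def mean_function(config: GeneratorConfig, t: np.ndarray) -> np.ndarray:
    """Deterministic expected count at 1-based daily index ``t``
    (before noise, holidays, clipping and rounding)."""
    t = np.asarray(t, dtype=float)
    tau = ((t - 1) % 7).astype(int)  # 0-based weekday column
    profile = np.asarray(config.weekday_profile)
    return ((config.base_level + config.trend_slope * t)
            * profile[tau]
            * (1.0 + config.annual_amplitude * np.sin(2 * np.pi * t / 364.0)))


def generate_series(config: GeneratorConfig) -> DailyCountSeries:
    """Generate ``config.n_weeks`` whole weeks of synthetic daily counts.

    The first date is a Monday; the output is deterministic given
    ``config.seed``.
    """
    n = int(config.n_weeks) * 7
    t = np.arange(1, n + 1)
    mu = mean_function(config, t)
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
    y = mu + noise
    if config.holiday_rate > 0:
        holidays = rng.random(n) < config.holiday_rate
        y = np.where(holidays, y * config.holiday_factor, y)
    y = np.round(np.clip(y, 0.0, None))
    start = pd.Timestamp(config.start_date)
    if start.dayofweek != 0:
        raise ValueError(f"start_date must be a Monday, got "
                         f"{start.day_name()}")
    dates = pd.date_range(start, periods=n, freq="D")
    return DailyCountSeries(dates, y)


def inject_singularities(series: DailyCountSeries, k: int,
                         magnitude: float, seed: int):
    """Perturb ``k`` days to lie beyond ``magnitude`` weekday-column SDs.

    Picks ``k`` distinct (week, weekday) cells — spread across weekday
    columns to avoid one outlier masking another — and moves each beyond
    mean +/- magnitude*SD of the *other* weeks of its weekday sub-series,
    escalating the offset until the perturbed panel's own column statistics
    also place the point beyond magnitude SDs (matching how the outlier
    detector will see it).  Returns the perturbed series and the 1-based
    ``(week, weekday)`` positions as ground truth.

    ``magnitude`` must exceed 2 so injected points are genuine outliers
    under the standard 2-SD screening rule.  Note a hard limit of sample
    statistics: a single point in an n-week column can sit at most
    (n-1)/sqrt(n) sample SDs from the column mean, so detectability under
    the perturbed column's own statistics is guaranteed only when
    n > magnitude**2 (e.g. >= 11 weeks for magnitude 3); on shorter panels
    the offset is still placed beyond the leave-one-out threshold.
    """
    if k < 0 or k > len(series):
        raise ValueError(f"k={k} outside 0..len(series)={len(series)}")
    if magnitude <= 2:
        raise ValueError(f"magnitude must exceed 2, got {magnitude}")
    if k == 0:
        return series, []
    panel = to_panel(series)
    values = panel.values.copy()
    n_weeks = values.shape[0]
    rng = np.random.default_rng(seed)

    # round-robin over shuffled weekday columns, random week within column
    cols = rng.permutation(7)
    positions: list[tuple[int, int]] = []
    used: set[tuple[int, int]] = set()
    i = 0
    while len(positions) < k:
        col = int(cols[i % 7])
        free = [w for w in range(n_weeks) if (w, col) not in used]
        i += 1
        if not free:
            continue
        w = int(rng.choice(free))
        used.add((w, col))
        positions.append((w, col))

    signs = rng.choice((-1.0, 1.0), size=k)
    for (w, col), sign in zip(positions, signs):
        column = values[:, col]
        others = np.delete(column, w)
        base_sd = float(np.std(others, ddof=1)) if len(others) > 1 else 0.0
        floor = max(1.0, 0.25 * float(np.mean(np.abs(others)) or 1.0))
        delta = magnitude * max(base_sd, floor) * 1.01
        n_col = len(column)
        feasible = n_col > 1 and (n_col - 1) / np.sqrt(n_col) > magnitude
        for _ in range(60):
            candidate = float(np.mean(others)) + sign * delta
            if candidate < 0:  # counts are non-negative; push upward instead
                sign = 1.0
                candidate = float(np.mean(others)) + delta
            column[w] = candidate
            if not feasible:
                break
            m, s = float(np.mean(column)), float(np.std(column, ddof=1))
            if s > 0 and abs(column[w] - m) > magnitude * s:
                break
            delta *= 1.6

    out = series.replace_counts(values.reshape(-1))
    return out, [(w + 1, c + 1) for w, c in positions]
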