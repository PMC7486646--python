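"""Daily count series and the week x weekday panel view.

The observed process is a daily count series Y_t (t = 1, 2, ...) that is
strongly weekly-periodic.  Most of the pipeline works on a reshaped view:
a panel with one row per ISO week (Monday-first) and one column per weekday,
linked to the daily index by

    t = 7 * (t' - 1) + tau,        t' = week index (1-based), tau = 1..7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailyCountSeries",
    "WeekdayPanel",
    "trim_to_whole_weeks",
    "to_panel",
    "from_panel",
    "read_series",
    "write_series",
]

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass(frozen=True)
class DailyCountSeries:
    """A gap-free, date-indexed daily count series.

    Parameters
    ----------
    dates
        Strictly consecutive calendar days.
    counts
        One non-negative count per day.
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or len(dates) != len(counts):
            raise ValueError("counts must be 1-D and match dates in length")
        if len(dates) == 0:
            raise ValueError("series is empty")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            i = int(np.argmax(deltas != 1))
            missing = dates[i] + pd.Timedelta(days=1)
            raise ValueError(f"dates must be consecutive days; gap after "
                             f"{dates[i].date()} (missing {missing.date()})")
        if np.any(counts < 0):
            i = int(np.argmax(counts < 0))
            raise ValueError(f"negative count {counts[i]} at {dates[i].date()}")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def weekdays(self) -> np.ndarray:
        """Weekday index tau in 1..7, Monday = 1."""
        return self.dates.dayofweek.to_numpy() + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"),
                             "count": self.counts})

    def replace_counts(self, counts: np.ndarray) -> "DailyCountSeries":
        return DailyCountSeries(self.dates, counts)


@dataclass(frozen=True)
class WeekdayPanel:
    """Week-by-weekday matrix view of a daily series.

    ``values[w, j]`` is the count of weekday ``j`` (0-based column, Monday
    first) in week ``w`` (0-based row); in 1-based (t', tau) terms it is the
    daily observation at t = 7*(t'-1) + tau.
    """

    values: np.ndarray
    start_date: pd.Timestamp = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 7:
            raise ValueError("panel must be a (n_weeks, 7) matrix")
        object.__setattr__(self, "values", values)

    @property
    def n_weeks(self) -> int:
        return self.values.shape[0]

    def column(self, tau: int) -> np.ndarray:
        """Sub-series of weekday tau (1..7) across weeks."""
        if not 1 <= tau <= 7:
            raise ValueError(f"weekday index tau must be in 1..7, got {tau}")
        return self.values[:, tau - 1]

    def to_series(self) -> DailyCountSeries:
        return from_panel(self)


def trim_to_whole_weeks(series: DailyCountSeries) -> DailyCountSeries:
    """Drop partial leading/trailing weeks, keeping first Monday .. last Sunday.

    Data from incomplete weekly cycles would break the panel view, so they
    are excluded before any analysis.
    """
    wd = series.weekdays
    mondays = np.flatnonzero(wd == 1)
    sundays = np.flatnonzero(wd == 7)
    if len(mondays) == 0 or len(sundays) == 0 or sundays[-1] < mondays[0]:
        raise ValueError("series contains no whole Monday-Sunday week")
    start, stop = mondays[0], sundays[-1] + 1
    return DailyCountSeries(series.dates[start:stop], series.counts[start:stop])


def to_panel(series: DailyCountSeries) -> WeekdayPanel:
    """Reshape a whole-weeks series into a (n_weeks, 7) panel.

    The series must start on a Monday and span whole weeks; use
    :func:`trim_to_whole_weeks` first otherwise.
    """
    if series.weekdays[0] != 1:
        raise ValueError(f"series must start on a Monday, "
                         f"got {series.dates[0].day_name()}")
    if len(series) % 7 != 0:
        raise ValueError(f"series length {len(series)} is not a multiple of 7")
    return WeekdayPanel(series.counts.reshape(-1, 7), series.dates[0])


def from_panel(panel: WeekdayPanel) -> DailyCountSeries:
    """Inverse of :func:`to_panel` (requires the panel's start date)."""
    if panel.start_date is None:
        raise ValueError("panel carries no start date; cannot rebuild series")
    n = panel.values.size
    dates = pd.date_range(panel.start_date, periods=n, freq="D")
    return DailyCountSeries(dates, panel.values.reshape(-1))


def read_series(path) -> DailyCountSeries:
    """Read a ``date,count`` CSV into a validated series.

    Rows must be one per calendar day; duplicate dates, gaps, negative counts
    and malformed dates are rejected with row-numbered messages.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["date", "count"]:
        raise ValueError(f"{path}: expected header 'date,count', "
                         f"got {list(df.columns)}")
    try:
        dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed date ({exc})") from exc
    order = np.argsort(dates.values, kind="stable")
    dates = pd.DatetimeIndex(dates.values[order])
    counts = df["count"].to_numpy(dtype=float)[order]
    dup = dates.duplicated()
    if dup.any():
        i = int(np.argmax(dup))
        raise ValueError(f"{path}: duplicate date {dates[i].date()} "
                         f"(row {order[i] + 2})")
    if np.any(counts < 0):
        i = int(np.argmax(counts < 0))
        raise ValueError(f"{path}: negative count at row {order[i] + 2} "
                         f"({dates[i].date()})")
    return DailyCountSeries(dates, counts)


def write_series(series: DailyCountSeries, path) -> None:
    """Write the series as a ``date,count`` CSV with ISO-8601 dates."""
    df = series.to_frame()
    df["count"] = df["count"].map(
        lambda v: int(v) if float(v).is_integer() else v)
    df.to_csv(path, index=False)
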