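"""Outlier screening and replacement on the weekly panel.

Daily blood-collection counts carry holiday-driven "singularities": days
whose volume is far from what their weekday usually sees (a public holiday
Monday can look like a Sunday).  Because each weekday has its own level,
screening is done per weekday column: a cell is flagged when it lies more
than ``sd_multiple`` (default 2) sample standard deviations from its
column mean.  Flagged cells are replaced by the average of the same weekday
in the nearest clean neighbouring weeks, preserving the weekly cycle.
"""

from __future__ import annotations

import numpy as np

from .series import WeekdayPanel

__all__ = ["detect_singularities", "replace_singularities", "clean_panel"]


def detect_singularities(panel: WeekdayPanel,
                         sd_multiple: float = 2.0) -> list[tuple[int, int]]:
    """Flag cells beyond ``sd_multiple`` SDs of their weekday column.

    Thresholds use each column's mean and sample (n-1) standard deviation,
    computed once on the panel as given (a single pass; thresholds are not
    re-derived after replacements).  Returns 1-based ``(week, weekday)``
    pairs in row-major order.

    Requires at least 3 weeks so the column SD is meaningful.
    """
    if panel.n_weeks < 3:
        raise ValueError(f"need >= 3 weeks to screen outliers, "
                         f"got {panel.n_weeks}")
    v = panel.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    mask = np.abs(v - mean) > sd_multiple * sd
    return [(int(w) + 1, int(c) + 1) for w, c in np.argwhere(mask)]


def replace_singularities(panel: WeekdayPanel,
                          flagged: list[tuple[int, int]],
                          mode: str = "nearest") -> WeekdayPanel:
    """Replace flagged cells by same-weekday clean-neighbour averages.

    mode="nearest" (default): each flagged cell becomes the mean of the same
    weekday in the nearest non-flagged earlier week and the nearest
    non-flagged later week; at the panel boundary the two nearest clean
    values on the existing side are used.  mode="preceding": the mean of the
    two nearest non-flagged *earlier* weeks (falling back to later weeks
    near the start).

    All other cells are untouched; the panel shape is preserved.
    """
    if mode not in ("nearest", "preceding"):
        raise ValueError(f"unknown replacement mode {mode!r}")
    values = panel.values.copy()
    n_weeks = values.shape[0]
    flagged_set = {(w - 1, c - 1) for w, c in flagged}
    for w, c in sorted(flagged_set):
        if not (0 <= w < n_weeks and 0 <= c < 7):
            raise ValueError(f"flagged cell ({w + 1}, {c + 1}) outside panel")
        earlier = [i for i in range(w - 1, -1, -1) if (i, c) not in flagged_set]
        later = [i for i in range(w + 1, n_weeks) if (i, c) not in flagged_set]
        if mode == "preceding":
            donors = earlier[:2]
            if len(donors) < 2:
                donors += later[:2 - len(donors)]
        else:
            donors = []
            if earlier:
                donors.append(earlier[0])
            if later:
                donors.append(later[0])
            if len(donors) < 2:  # boundary: take two nearest on one side
                side = later if later else earlier
                donors = side[:2]
        if not donors:
            raise ValueError(f"no clean donor weeks for weekday {c + 1}")
        values[w, c] = float(np.mean([panel.values[i, c] for i in donors]))
    return WeekdayPanel(values, panel.start_date)


def clean_panel(panel: WeekdayPanel, sd_multiple: float = 2.0,
                mode: str = "nearest"):
    """Screen and replace in one step; returns (cleaned panel, flags)."""
    flags = detect_singularities(panel, sd_multiple)
    return replace_singularities(panel, flags, mode), flags
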