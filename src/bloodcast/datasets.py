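"""Bundled worked example: one published forecast week.

A hospital case study of this pipeline printed, for a single test week, the
observed Monday-Sunday collection counts, the week-ahead predictions of the
differenced moving-average model and of the per-weekday smoothers, the
smoothing constants used, and the combination weights (0.73, 0.27).  Those
numbers are bundled here as an input fixture so the combination and scoring
stages can be demonstrated and checked end to end with no external data.
The component forecasts are consumed as given — they are inputs to the
combination arithmetic, not outputs reproduced from the (unavailable)
underlying series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReferenceWeek", "reference_week"]


@dataclass(frozen=True)
class ReferenceWeek:
    """Observed counts and matched component forecasts, Monday..Sunday."""

    observed: np.ndarray
    pred_arima: np.ndarray
    pred_ses: np.ndarray
    ses_alphas: np.ndarray
    w1: float
    w2: float


def reference_week() -> ReferenceWeek:
    """The bundled single-week worked example."""
    return ReferenceWeek(
        observed=np.array([5387., 5155., 5095., 4862., 4003., 2401., 755.]),
        pred_arima=np.array([5337., 5147., 5091., 4997., 4034., 2369., 625.]),
        pred_ses=np.array([5377., 5191., 5120., 4954., 3918., 2313., 627.]),
        ses_alphas=np.array([0.099, 0.200, 0.006, 0.100, 0.003, 0.027, 0.199]),
        w1=0.73,
        w2=0.27,
    )
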