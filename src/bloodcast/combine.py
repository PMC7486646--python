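"""Residual-correction combination of the two component forecasts.

The combined forecast is the convex blend

    Y_hat = W1 * Y_hat_arima + W2 * Y_hat_ses,      W1 + W2 = 1,

with weights estimated from the two models' historical one-step residuals
on a common fitting window.  The default estimator is constrained least
squares: minimise sum_t (W1 e1_t + W2 e2_t)^2 subject to W1 + W2 = 1 (a
one-dimensional quadratic with a closed form), then clip to [0, 1] and
renormalise so the combination stays convex.  Two standard alternatives
are available: inverse-error weighting (w_i proportional to 1/error_i) and
the covariance-aware variance-minimising rule of Bates and Granger,
w1 = (s2^2 - s12) / (s1^2 + s2^2 - 2 s12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CombinationWeights", "CombinedForecast", "estimate_weights",
           "combine"]

METHODS = ("cls", "inverse-error", "bates-granger")


@dataclass(frozen=True)
class CombinationWeights:
    """Convex combination weights for (ARIMA, SES), summing to one."""

    w1: float
    w2: float
    method: str = "manual"
    window: tuple | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.w1 + self.w2, 1.0, atol=1e-12):
            raise ValueError(f"weights must sum to 1, got "
                             f"{self.w1} + {self.w2}")


@dataclass(frozen=True)
class CombinedForecast:
    """The week-ahead combined prediction with its components."""

    combined: np.ndarray
    pred_arima: np.ndarray
    pred_ses: np.ndarray
    weights: CombinationWeights


def _clip_renormalise(w1: float) -> tuple[float, float]:
    w1 = min(max(w1, 0.0), 1.0)
    return w1, 1.0 - w1


def estimate_weights(resid_arima, resid_ses, method: str = "cls",
                     window=None) -> CombinationWeights:
    """Estimate combination weights from aligned residual sequences.

    ``resid_arima`` and ``resid_ses`` are the one-step errors of the two
    models over the same fitting window, in the same order.  When the two
    residual vectors are identical the objective is flat and (0.5, 0.5) is
    returned with a warning.
    """
    e1 = np.asarray(resid_arima, dtype=float)
    e2 = np.asarray(resid_ses, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1:
        raise ValueError("residual sequences must be equal-length 1-D arrays")
    if len(e1) == 0:
        raise ValueError("residual sequences are empty")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")

    if np.array_equal(e1, e2):
        warnings.warn("identical residual sequences: combination weights "
                      "are undetermined, returning (0.5, 0.5)", stacklevel=2)
        return CombinationWeights(0.5, 0.5, method=method, window=window)

    if method == "cls":
        # minimise ||e2 + w1 (e1 - e2)||^2 over w1
        d = e1 - e2
        w1 = float(-np.dot(e2, d) / np.dot(d, d))
    elif method == "inverse-error":
        m1, m2 = float(np.mean(np.abs(e1))), float(np.mean(np.abs(e2)))
        if m1 == 0.0 and m2 == 0.0:
            w1 = 0.5
        elif m1 == 0.0:
            w1 = 1.0
        elif m2 == 0.0:
            w1 = 0.0
        else:
            w1 = (1.0 / m1) / (1.0 / m1 + 1.0 / m2)
    else:  # bates-granger
        s1 = float(np.var(e1))
        s2 = float(np.var(e2))
        s12 = float(np.mean((e1 - e1.mean()) * (e2 - e2.mean())))
        denom = s1 + s2 - 2.0 * s12
        w1 = 0.5 if denom == 0.0 else (s2 - s12) / denom

    w1, w2 = _clip_renormalise(w1)
    return CombinationWeights(w1, w2, method=method, window=window)


def combine(pred_arima, pred_ses, weights: CombinationWeights) -> CombinedForecast:
    """Form the elementwise weighted forecast W1*Y1 + W2*Y2.

    No rounding is applied; reporting layers round for display.
    """
    p1 = np.asarray(pred_arima, dtype=float)
    p2 = np.asarray(pred_ses, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"prediction vectors differ in shape: "
                         f"{p1.shape} vs {p2.shape}")
    return CombinedForecast(combined=weights.w1 * p1 + weights.w2 * p2,
                            pred_arima=p1, pred_ses=p2, weights=weights)
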