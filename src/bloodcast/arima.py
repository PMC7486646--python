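"""Seasonal-difference moving-average modelling of daily counts.

The daily series is made stationary by differencing — one regular pass to
remove trend and one lag-7 seasonal pass to remove the weekly cycle by
default — and the differenced series w_t is modelled as a pure moving
average,

    w_t = Theta(B) eps_t,      Theta(B) = 1 - theta_1 B - ... - theta_q B^q,

with eps_t white noise (no autoregressive part and no intercept: the
differencing removes the level).  Estimation is conditional least squares:
pre-sample innovations are fixed at zero, the innovation recursion is run as
a linear filter, and the sum of squared innovations is minimised by
quasi-Newton iteration over an invertibility-preserving reparameterisation.
Order q is selected by BIC, adequacy is checked with the Ljung-Box
portmanteau test, and forecasts are produced on the differenced scale
(future innovations set to their zero mean) then mapped back to counts by
exactly inverting the differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "DifferenceSpec",
    "difference",
    "invert_difference",
    "acf",
    "pacf",
    "MAFit",
    "MAFitError",
    "fit_ma",
    "select_order",
    "LjungBoxResult",
    "ljung_box",
    "forecast_arima",
]


# ---------------------------------------------------------------------------
# differencing

@dataclass(frozen=True)
class DifferenceSpec:
    """Differencing orders: ``d`` regular passes and ``D`` seasonal passes
    at period ``s`` (7 days throughout this package)."""

    d: int = 1
    D: int = 1
    s: int = 7

    def __post_init__(self) -> None:
        if self.d < 0 or self.D < 0:
            raise ValueError("difference orders d, D must be >= 0")
        if self.s < 1:
            raise ValueError("seasonal period s must be >= 1")

    @property
    def burn_in(self) -> int:
        """Observations consumed by the differencing."""
        return self.d + self.D * self.s

    def polynomial(self) -> np.ndarray:
        """Coefficients of (1-B)^d (1-B^s)^D as a backshift polynomial."""
        poly = np.array([1.0])
        for _ in range(self.d):
            poly = np.convolve(poly, [1.0, -1.0])
        sstep = np.zeros(self.s + 1)
        sstep[[0, self.s]] = (1.0, -1.0)
        for _ in range(self.D):
            poly = np.convolve(poly, sstep)
        return poly


def difference(series, spec: DifferenceSpec) -> np.ndarray:
    """Apply the regular and seasonal difference operators.

    Output length is ``len(series) - spec.burn_in``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) <= spec.burn_in:
        raise ValueError(f"series of length {len(x)} too short for "
                         f"burn-in {spec.burn_in}")
    for _ in range(spec.d):
        x = np.diff(x)
    for _ in range(spec.D):
        x = x[spec.s:] - x[:-spec.s]
    return x


def invert_difference(diffs, history, spec: DifferenceSpec) -> np.ndarray:
    """Exactly invert :func:`difference`.

    ``history`` must hold the ``spec.burn_in`` original-scale values
    immediately preceding the first element of ``diffs``.  Writing the
    differencing operator as the polynomial ``sum_j c_j B^j`` (c_0 = 1),
    each level value is recovered by

        y_t = w_t - sum_{j>=1} c_j y_{t-j}.

    Round-trip identity: ``invert_difference(difference(y, spec),
    y[:spec.burn_in], spec)`` equals ``y[spec.burn_in:]``; for forecasting,
    pass the tail of the observed series as history and the forecast
    differences as ``diffs``.
    """
    w = np.asarray(diffs, dtype=float)
    hist = np.asarray(history, dtype=float)
    m = spec.burn_in
    if len(hist) < m:
        raise ValueError(f"history must supply the last {m} original "
                         f"values, got {len(hist)}")
    if m == 0:
        return w.copy()
    poly = spec.polynomial()  # length m + 1, poly[0] == 1
    buf = np.concatenate([hist[-m:], np.zeros(len(w))])
    for i, wt in enumerate(w):
        t = m + i
        buf[t] = wt - np.dot(poly[1:], buf[t - 1::-1][:m])
    return buf[m:]


# ---------------------------------------------------------------------------
# correlograms

def acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelations r_1..r_max_lag (denominator n, overall mean).

    A constant series has no defined autocorrelation; NaNs are returned.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return np.full(max_lag, np.nan)
    return np.array([np.dot(xc[k:], xc[:-k]) / denom
                     for k in range(1, max_lag + 1)])


def pacf(series, max_lag: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin-Levinson recursion."""
    r = acf(series, max_lag)
    if np.any(np.isnan(r)):
        return np.full(max_lag, np.nan)
    pac = np.zeros(max_lag)
    phi_prev = np.zeros(0)
    for k in range(1, max_lag + 1):
        if k == 1:
            phi_k = np.array([r[0]])
        else:
            num = r[k - 1] - np.dot(phi_prev, r[k - 2::-1][:k - 1])
            den = 1.0 - np.dot(phi_prev, r[:k - 1])
            a = num / den if den != 0 else 0.0
            phi_k = np.concatenate([phi_prev - a * phi_prev[::-1], [a]])
        pac[k - 1] = phi_k[-1]
        phi_prev = phi_k
    return pac


# ---------------------------------------------------------------------------
# conditional least squares MA fitting

class MAFitError(RuntimeError):
    """Raised when the CSS optimiser fails to converge; carries the
    optimiser's diagnostic message."""


@dataclass(frozen=True)
class MAFit:
    """A fitted pure moving-average model on the differenced scale.

    Sign convention: Theta(B) = 1 - theta_1 B - ... - theta_q B^q, so a
    positive one-lag dependence appears as a *negative* theta_1 (matching
    the output of standard statistical software).
    """

    q: int
    theta: np.ndarray
    sigma2: float
    residuals: np.ndarray
    loglik: float
    bic: float
    n_obs: int
    se: np.ndarray = field(default=None)
    t_values: np.ndarray = field(default=None)

    def ma_poly(self) -> np.ndarray:
        """Theta as filter coefficients [1, -theta_1, ..., -theta_q]."""
        return np.concatenate([[1.0], -self.theta])


def _raw_to_ma(raw: np.ndarray) -> np.ndarray:
    """Map unconstrained parameters to an invertible MA polynomial's
    coefficients a_1..a_q (convention w_t = eps_t + sum a_j eps_{t-j}),
    via partial-coefficient recursion with a tanh squash."""
    pac = np.tanh(raw / 2.0)
    q = len(pac)
    a = np.zeros(q)
    for j in range(q):
        prev = a[:j].copy()
        a[j] = pac[j]
        a[:j] = prev + pac[j] * prev[::-1]
    return a


def _css_residuals(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Innovations of w_t = eps_t + sum a_j eps_{t-j}, pre-sample eps = 0."""
    return signal.lfilter([1.0], np.concatenate([[1.0], a]), w)


def fit_ma(diff_series, q: int, maxiter: int = 500) -> MAFit:
    """Fit an MA(q) model to a differenced series by conditional least
    squares.

    Minimises the sum of squared innovations with pre-sample innovations
    fixed at zero, over an invertibility-preserving reparameterisation
    started at white noise (all coefficients zero).  Returns the
    coefficient estimates, the innovation variance sigma^2 = SSE/n, the
    Gaussian log-likelihood, BIC = n ln(sigma^2) + (q+1) ln(n), and
    t statistics from numerical-Hessian standard errors.

    Raises :class:`MAFitError` on optimiser failure — a fit is never
    returned silently from a failed search.
    """
    w = np.asarray(diff_series, dtype=float)
    n = len(w)
    if q < 1:
        raise ValueError("q must be >= 1")
    if n <= 3 * q:
        raise ValueError(f"need more than 3q = {3 * q} observations, got {n}")

    def sse(raw: np.ndarray) -> float:
        eps = _css_residuals(_raw_to_ma(raw), w)
        return float(np.dot(eps, eps))

    res = optimize.minimize(sse, np.zeros(q), method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-7})
    if not res.success and res.status != 2:
        # status 2 = precision loss at an already-converged point; anything
        # else is a genuine failure
        raise MAFitError(f"CSS optimisation failed for MA({q}): "
                         f"{res.message} (nit={res.nit}, sse={res.fun:.6g})")
    a = _raw_to_ma(res.x)
    theta = -a
    eps = _css_residuals(a, w)
    sigma2 = float(np.dot(eps, eps)) / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    bic = n * np.log(sigma2) + (q + 1) * np.log(n)

    se, t_values = _theta_standard_errors(theta, w, sigma2)
    return MAFit(q=q, theta=theta, sigma2=sigma2, residuals=eps,
                 loglik=loglik, bic=bic, n_obs=n, se=se, t_values=t_values)


def _theta_standard_errors(theta: np.ndarray, w: np.ndarray, sigma2: float):
    """Central-difference Hessian of the CSS objective in theta space;
    cov(theta) ~ sigma^2 * (H/2)^{-1}."""
    q = len(theta)

    def sse_theta(th: np.ndarray) -> float:
        eps = _css_residuals(-th, w)
        return float(np.dot(eps, eps))

    h = 1e-4
    hess = np.zeros((q, q))
    f0 = sse_theta(theta)
    for i in range(q):
        for j in range(i, q):
            ei = np.zeros(q); ei[i] = h
            ej = np.zeros(q); ej[j] = h
            if i == j:
                val = (sse_theta(theta + ei) - 2 * f0
                       + sse_theta(theta - ei)) / h ** 2
            else:
                val = (sse_theta(theta + ei + ej) - sse_theta(theta + ei - ej)
                       - sse_theta(theta - ei + ej)
                       + sse_theta(theta - ei - ej)) / (4 * h ** 2)
            hess[i, j] = hess[j, i] = val
    try:
        cov = sigma2 * np.linalg.inv(hess / 2.0)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        se = np.sqrt(var)
        return se, theta / se
    except np.linalg.LinAlgError:
        return None, None


def select_order(diff_series, q_candidates) -> int:
    """Return the MA order with minimal BIC; ties go to the smaller order.

    Candidates whose fit fails are skipped; if every candidate fails, the
    per-candidate failure messages are raised together.
    """
    candidates = sorted(set(int(q) for q in q_candidates))
    if not candidates:
        raise ValueError("q_candidates is empty")
    best_q, best_bic = None, np.inf
    failures: list[str] = []
    for q in candidates:
        try:
            fit = fit_ma(diff_series, q)
        except (MAFitError, ValueError) as exc:
            failures.append(f"q={q}: {exc}")
            continue
        if fit.bic < best_bic - 1e-12:
            best_q, best_bic = q, fit.bic
    if best_q is None:
        raise MAFitError("all candidate orders failed:\n" + "\n".join(failures))
    return best_q


# ---------------------------------------------------------------------------
# diagnostics

@dataclass(frozen=True)
class LjungBoxResult:
    """One row of the portmanteau table: Q statistic at a lag, degrees of
    freedom (lag minus fitted MA parameters, floored at 0), and the
    upper-tail chi-square p-value (absent when df = 0)."""

    lag: int
    q_stat: float
    df: int
    p_value: float | None


def ljung_box(residuals, lags, n_fitted_params: int = 0) -> list[LjungBoxResult]:
    """Ljung-Box portmanteau test on a residual sequence.

    Q(lag) = n (n+2) sum_{k=1}^{lag} r_k^2 / (n - k), referred to a
    chi-square with ``lag - n_fitted_params`` degrees of freedom.  Rows with
    zero degrees of freedom report no p-value.
    """
    eps = np.asarray(residuals, dtype=float)
    n = len(eps)
    lags = [int(l) for l in lags]
    if max(lags) >= n:
        raise ValueError(f"max lag {max(lags)} must be < residual length {n}")
    r = acf(eps, max(lags))
    results = []
    for lag in lags:
        k = np.arange(1, lag + 1)
        q_stat = float(n * (n + 2) * np.sum(r[:lag] ** 2 / (n - k)))
        df = max(lag - n_fitted_params, 0)
        p = float(stats.chi2.sf(q_stat, df)) if df > 0 else None
        results.append(LjungBoxResult(lag=lag, q_stat=q_stat, df=df, p_value=p))
    if all(res.df == 0 for res in results):
        warnings.warn("all requested lags give zero degrees of freedom; "
                      "the portmanteau test is uninformative here",
                      stacklevel=2)
    return results


# ---------------------------------------------------------------------------
# forecasting

def forecast_arima(series, spec: DifferenceSpec, fit: MAFit,
                   horizon: int = 7) -> np.ndarray:
    """Forecast the next ``horizon`` days on the original count scale.

    The MA(q) forecasts on the differenced scale set future innovations to
    zero (so they vanish beyond lag q), and the differencing is inverted
    exactly against the tail of the observed series.  The forecast window
    is capped at 7 days, the horizon this pipeline is designed and
    validated for.
    """
    if not 1 <= horizon <= 7:
        raise ValueError(f"horizon must be in 1..7, got {horizon}")
    y = series.counts if hasattr(series, "counts") else np.asarray(series, float)
    w = difference(y, spec)
    # innovations recomputed on this exact series to guarantee alignment
    eps = _css_residuals(-fit.theta, w)
    a = -fit.theta  # w_t = eps_t + sum a_j eps_{t-j}
    q = fit.q
    eps_ext = np.concatenate([eps, np.zeros(horizon)])
    n = len(w)
    w_hat = np.zeros(horizon)
    for h in range(1, horizon + 1):
        past = [a[j - 1] * eps_ext[n + h - 1 - j] for j in range(h, q + 1)]
        w_hat[h - 1] = float(np.sum(past)) if past else 0.0
    return invert_difference(w_hat, y[-spec.burn_in:] if spec.burn_in else y[:0],
                             spec)
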