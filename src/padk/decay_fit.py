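"""First-order decay fitting with optional lag and 95% confidence intervals.

Shared by the reporter (RT-qPCR-style), SLAM-seq and simulated-chase
analyses.  The models are

* plain exponential:  value = A₀·exp(−k·t)
* lag exponential:    value = A₀·exp(−k·(t−l)) for t ≥ l, A₀ for t < l

with half-life = ln(2)/k + l.  The lag l models the delay between the
transcription shut-off drug reaching the cell and decay actually starting;
the default 1.2 min is the wild-type reporter estimate.  Goodness of fit is
a pseudo-R² (1 − SSres/SStot), and confidence intervals on k come from
profile-likelihood inversion with a Wald fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import f as f_dist

__all__ = [
    "DecaySeries",
    "DecayFit",
    "fit_exponential",
    "fit_lag_exponential",
    "pseudo_r2",
    "confidence_interval",
    "DEFAULT_LAG_MIN",
]

#: Default lag (min) applied to reporter decay fits.
DEFAULT_LAG_MIN = 1.2


@dataclass(frozen=True)
class DecaySeries:
    """A normalized decay time course: value 1 at t = 0, strictly positive."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(np.unique(t)) < 3:
            raise ValueError("need at least 3 distinct time points")
        if not np.any(t == 0):
            raise ValueError("series must contain t = 0")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(v <= 0):
            raise ValueError("values must be positive")


@dataclass(frozen=True)
class DecayFit:
    """Result of a first-order decay fit."""

    k: float
    lag: float
    a0: float
    half_life: float
    pseudo_r2: float
    sse: float
    k_ci_low: float = math.nan
    k_ci_high: float = math.nan
    ci_method: str = "none"
    n_params: int = 2
    success: bool = True
    message: str = ""

    @property
    def half_life_ci(self) -> tuple[float, float]:
        """95% CI on half-life from the k interval (monotone transform)."""
        return (
            math.log(2.0) / self.k_ci_high + self.lag,
            math.log(2.0) / self.k_ci_low + self.lag,
        )


def _model(t: np.ndarray, a0: float, k: float, lag: float) -> np.ndarray:
    # plateau before the lag: decay has not started yet
    return a0 * np.exp(-k * np.clip(t - lag, 0.0, None))


def _failed(message: str, lag: float = 0.0) -> DecayFit:
    return DecayFit(
        k=math.nan,
        lag=lag,
        a0=math.nan,
        half_life=math.nan,
        pseudo_r2=math.nan,
        sse=math.nan,
        success=False,
        message=message,
    )


def _init_k(series: DecaySeries, lag: float) -> tuple[float, float]:
    """Log-linear initialization: regress log(value) on max(t-lag, 0)."""
    x = np.clip(series.times - lag, 0.0, None)
    y = np.log(series.values)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        return math.nan, math.nan
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    a0 = math.exp(y.mean() - slope * x.mean())
    return -slope, a0


def fit_lag_exponential(
    series: DecaySeries,
    lag: float = DEFAULT_LAG_MIN,
    fit_lag: bool = False,
    ci: bool = True,
    level: float = 0.95,
) -> DecayFit:
    """Fit value = A₀·exp(−k·(t−l)) with the lag fixed (default) or free.

    With ``lag=0`` this is exactly the plain exponential fit.  Half-life is
    ln(2)/k + l.  Failures (non-convergence, k ≤ 0) are returned as flagged
    fits rather than raised, so batch pipelines can audit them.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if fit_lag and len(np.unique(series.times)) < 4:
        raise ValueError("fitting the lag requires at least 4 time points")

    if float(np.var(series.values)) == 0.0:
        return _failed("zero-variance series: no decay to fit", lag)

    k0, a00 = _init_k(series, lag)
    if not (np.isfinite(k0) and k0 > 0):
        # flat or increasing series: no meaningful positive decay rate
        k0, a00 = 1e-3, float(series.values[series.times == 0][0])

    t, y = series.times, series.values

    if fit_lag:
        def resid(p: np.ndarray) -> np.ndarray:
            return _model(t, p[0], p[1], p[2]) - y

        x0 = np.array([a00, k0, lag])
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
        n_par = 3
    else:
        def resid(p: np.ndarray) -> np.ndarray:
            return _model(t, p[0], p[1], lag) - y

        x0 = np.array([a00, k0])
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        n_par = 2

    sol = least_squares(
        resid, x0, bounds=bounds, method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        return _failed(f"least squares did not converge: {sol.message}", lag)
    a0_hat, k_hat = float(sol.x[0]), float(sol.x[1])
    lag_hat = float(sol.x[2]) if fit_lag else lag
    if k_hat <= 0 or not np.isfinite(k_hat):
        return _failed("fitted decay rate is not positive", lag_hat)

    sse = float(np.sum(sol.fun**2))
    yhat = _model(t, a0_hat, k_hat, lag_hat)
    fit = DecayFit(
        k=k_hat,
        lag=lag_hat,
        a0=a0_hat,
        half_life=math.log(2.0) / k_hat + lag_hat,
        pseudo_r2=_pseudo_r2_arrays(y, yhat),
        sse=sse,
        n_params=n_par,
    )
    if ci:
        lo, hi, method = _k_interval(series, fit, n_par, level)
        fit = replace(fit, k_ci_low=lo, k_ci_high=hi, ci_method=method)
    return fit


def fit_exponential(series: DecaySeries, ci: bool = True, level: float = 0.95) -> DecayFit:
    """Fit value = A₀·exp(−k·t) (no lag)."""
    return fit_lag_exponential(series, lag=0.0, fit_lag=False, ci=ci, level=level)


def _pseudo_r2_arrays(y: np.ndarray, yhat: np.ndarray) -> float:
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("pseudo-R² undefined for a zero-variance series")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def pseudo_r2(series: DecaySeries, fit: DecayFit) -> float:
    """1 − SSres/SStot for the fitted curve; may be < 0 for bad fits."""
    if not fit.success:
        raise ValueError("pseudo-R² requires a successful fit")
    yhat = _model(series.times, fit.a0, fit.k, fit.lag)
    return _pseudo_r2_arrays(series.values, yhat)


def _profile_sse(series: DecaySeries, k: float, lag: float) -> float:
    """SSE at fixed k with the amplitude profiled out (linear in A₀)."""
    m = np.exp(-k * np.clip(series.times - lag, 0.0, None))
    denom = float(np.dot(m, m))
    a0 = float(np.dot(series.values, m)) / denom
    if a0 < 0:
        a0 = 0.0
    return float(np.sum((series.values - a0 * m) ** 2))


def _k_interval(
    series: DecaySeries, fit: DecayFit, n_par: int, level: float
) -> tuple[float, float, str]:
    """Profile-likelihood CI on k; Wald fallback; degenerate for perfect fits."""
    n = len(series.times)
    df = n - n_par
    if df <= 0:
        return math.nan, math.nan, "none"
    if fit.sse <= 1e-24:  # numerically perfect fit: interval collapses to k
        return fit.k, fit.k, "degenerate"

    # profile-t inversion: SSE(k) crosses sse_min * (1 + F(1, df)/df)
    crit = f_dist.ppf(level, 1, df)
    threshold = fit.sse * (1.0 + crit / df)

    def g(k: float) -> float:
        return _profile_sse(series, k, fit.lag) - threshold

    try:
        lo = _bracket_root(g, fit.k, direction=-1)
        hi = _bracket_root(g, fit.k, direction=+1)
        return lo, hi, "profile"
    except (ValueError, RuntimeError):
        pass

    # Wald fallback from the numerical curvature of the profile SSE
    try:
        h = max(1e-6, 1e-4 * fit.k)
        d2 = (
            _profile_sse(series, fit.k + h, fit.lag)
            - 2.0 * fit.sse
            + _profile_sse(series, fit.k - h, fit.lag)
        ) / h**2
        if d2 <= 0:
            raise RuntimeError("non-positive curvature")
        sigma2 = fit.sse / df
        se = math.sqrt(2.0 * sigma2 / d2)
        from scipy.stats import t as t_dist

        z = t_dist.ppf(0.5 + level / 2.0, df)
        return fit.k - z * se, fit.k + z * se, "wald"
    except (ValueError, RuntimeError, ZeroDivisionError):
        return math.nan, math.nan, "failed"


def _bracket_root(g, k_hat: float, direction: int) -> float:
    """Root of g on one side of k_hat; g(k_hat) < 0 by construction."""
    step = 0.5 * k_hat
    k = k_hat
    for _ in range(200):
        k_next = k + direction * step
        if k_next <= 0:
            k_next = k / 2.0
        if g(k_next) > 0:
            a, b = sorted((k_next, k_hat))
            return float(brentq(g, a, b, xtol=1e-12, maxiter=200))
        k = k_next
        step *= 1.6
    raise RuntimeError("failed to bracket the profile-likelihood root")


def confidence_interval(
    series: DecaySeries, fit: DecayFit, level: float = 0.95
) -> tuple[float, float]:
    """Recompute the CI on k at an arbitrary level (profile with Wald fallback)."""
    if not fit.success:
        raise ValueError("confidence interval requires a successful fit")
    lo, hi, _ = _k_interval(series, fit, n_par=fit.n_params, level=level)
    return lo, hi


def fit_series_batch(
    grouped: Sequence[tuple[object, DecaySeries]],
    lag: float = 0.0,
    level: float = 0.95,
):
    """Fit many series; yields (key, DecayFit) preserving failures."""
    for key, series in grouped:
        try:
            yield key, fit_lag_exponential(series, lag=lag, ci=True, level=level)
        except ValueError as exc:
            yield key, _failed(str(exc), lag)
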