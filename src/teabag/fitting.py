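"""Asymptotic-exponential fitting of mass-loss time series.

Fits m(t) = a*exp(-k t) + (1 - a) to a series of (day, remaining mass
fraction) observations by bounded nonlinear least squares, yielding the
observed initial rate (``k_hat``) and observed asymptote
(``asymptote_hat = 1 - a_hat``) that a direct time-series experiment
measures — the quantities the TBI closed forms try to predict from a
single harvest. The intercept is fixed at m(0) = 1: remaining masses are
fractions of the initial dry mass by construction.

Fitting is fully deterministic: a rule-based start (asymptote from the
smallest observed remaining mass, rate from an origin-constrained
log-linear regression) is augmented with a small fixed grid of fallback
starts, and the lowest-cost solution wins. Identical input therefore
yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import TeaType, mass_margin, remaining_fraction

__all__ = ["TimeSeries", "DecayFit", "fit_decay", "truncate", "fit_margin"]

A_BOUNDS = (1e-6, 1.0 - 1e-6)
K_BOUNDS = (1e-8, 10.0)
# Fixed fallback starts spanning slow/fast decay and small/large labile pools.
_EXTRA_STARTS = [(a0, k0) for a0 in (0.2, 0.5, 0.8) for k0 in (0.003, 0.02, 0.1)]


@dataclass(frozen=True, eq=False)
class TimeSeries:
    """Ordered (day, remaining-mass-fraction) observations for one bag series."""

    id: str
    tea_type: TeaType
    times: np.ndarray
    remaining: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tea_type", TeaType.parse(self.tea_type))
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.remaining, dtype=float)
        if t.ndim != 1 or y.shape != t.shape or t.size < 1:
            raise ValueError("times and remaining must be equal-length 1-D, length >= 1")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if np.any(y <= 0) or np.any(y > 1.2):
            raise ValueError("remaining fractions must lie in (0, 1.2]")
        t.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "remaining", y)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def t0_inconsistent(self) -> bool:
        """True when a day-0 observation exists but is not 1 (real-data quirk)."""
        return bool(self.times[0] == 0 and self.remaining[0] != 1.0)


@dataclass(frozen=True)
class DecayFit:
    """Two-pool fit of one time series; ``asymptote_hat`` is exactly 1 - a_hat."""

    id: str
    a_hat: float
    k_hat: float
    rss: float
    n_points: int
    converged: bool
    success: bool
    max_day: float
    k_rel_se: float = math.nan
    reason: str | None = None

    @property
    def asymptote_hat(self) -> float:
        return 1.0 - self.a_hat


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Deterministic start: a0 from the observed floor, k0 log-linear."""
    a0 = min(max(1.0 - float(np.min(y)), 0.05), 0.95)
    arg = (y - (1.0 - a0)) / a0
    mask = (arg > 1e-9) & (t > 0)
    k0 = 0.01
    if np.count_nonzero(mask) >= 2:
        tt, z = t[mask], -np.log(arg[mask])
        denom = float(np.sum(tt * tt))
        if denom > 0:
            k0 = float(np.sum(tt * z)) / denom
    return a0, min(max(k0, 1e-6), 5.0)


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, k = theta
    return a * np.exp(-k * t) + (1.0 - a) - y


def _jacobian(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, k = theta
    e = np.exp(-k * t)
    return np.column_stack([e - 1.0, -a * t * e])


def _failed(ts: TimeSeries, reason: str) -> DecayFit:
    return DecayFit(
        id=ts.id,
        a_hat=math.nan,
        k_hat=math.nan,
        rss=math.nan,
        n_points=len(ts),
        converged=False,
        success=False,
        max_day=float(ts.times[-1]),
        reason=reason,
    )


def fit_decay(ts: TimeSeries, *, max_k_rel_se: float = 1.0) -> DecayFit:
    """Fit the two-pool decay model to one series by bounded least squares.

    Minimises the sum of squared residuals over a in (0, 1), k in (0, 10]
    (day^-1) with a trust-region reflective solver. Never raises on numeric
    failure: degenerate series (constant or net-gaining mass) come back
    with ``success=False`` and reason ``UNIDENTIFIABLE``, too-short series
    with ``TOO_FEW_POINTS``. A successful fit additionally requires
    convergence, both parameters interior to their bounds, and a relative
    standard error of k below ``max_k_rel_se`` (default 100%).
    """
    t, y = ts.times, ts.remaining
    n = len(ts)
    if n < 4:
        return _failed(ts, "TOO_FEW_POINTS")
    if np.all(np.diff(y) >= 0):  # constant or mass-gaining: no decay signal
        return _failed(ts, "UNIDENTIFIABLE")

    starts = [_initial_guess(t, y)] + _EXTRA_STARTS
    best = None
    for a0, k0 in starts:
        a0 = min(max(a0, A_BOUNDS[0]), A_BOUNDS[1])
        k0 = min(max(k0, K_BOUNDS[0]), K_BOUNDS[1])
        res = least_squares(
            _residuals,
            x0=[a0, k0],
            jac=_jacobian,
            bounds=([A_BOUNDS[0], K_BOUNDS[0]], [A_BOUNDS[1], K_BOUNDS[1]]),
            method="trf",
            args=(t, y),
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None

    a_hat, k_hat = float(best.x[0]), float(best.x[1])
    rss = float(np.sum(best.fun**2))
    converged = bool(best.status > 0)

    eps = 1e-9
    interior = (
        A_BOUNDS[0] + eps < a_hat < A_BOUNDS[1] - eps
        and K_BOUNDS[0] + eps < k_hat < K_BOUNDS[1] - eps
    )

    k_rel_se = math.inf
    if n > 2:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / (n - 2))
            var_k = float(cov[1, 1])
            k_rel_se = math.sqrt(max(var_k, 0.0)) / k_hat if k_hat > 0 else math.inf
        except np.linalg.LinAlgError:
            pass

    success = converged and interior and n >= 4 and k_rel_se < max_k_rel_se
    reason = None
    if not success:
        if not converged:
            reason = "NOT_CONVERGED"
        elif not interior:
            reason = "AT_BOUNDS"
        else:
            reason = "UNCERTAIN_K"

    return DecayFit(
        id=ts.id,
        a_hat=a_hat,
        k_hat=k_hat,
        rss=rss,
        n_points=n,
        converged=converged,
        success=success,
        max_day=float(t[-1]),
        k_rel_se=k_rel_se,
        reason=reason,
    )


def truncate(ts: TimeSeries, max_day: float) -> TimeSeries:
    """Subseries with times <= max_day (id and tea type preserved).

    Used to study how the incubation length shifts the fitted asymptote and
    rate; an empty result is an error.
    """
    if max_day <= 0:
        raise ValueError(f"max_day must be > 0, got {max_day}")
    keep = ts.times <= max_day
    if not np.any(keep):
        raise ValueError(f"no observations at or before day {max_day}")
    return TimeSeries(
        id=ts.id, tea_type=ts.tea_type, times=ts.times[keep], remaining=ts.remaining[keep]
    )


def fit_margin(
    fit: DecayFit,
    at_day: float,
    ts: TimeSeries | None = None,
    *,
    mode: str = "model",
) -> float:
    """Mass margin (% of initial mass) of a fitted series at ``at_day``.

    ``mode="model"`` (default) evaluates the fitted curve at ``at_day``, so
    the margin is defined even between observation days;
    ``mode="observation"`` uses the raw observation nearest to ``at_day``
    (requires ``ts``).
    """
    if not fit.success:
        raise ValueError("fit_margin requires a successful fit")
    if at_day < 0:
        raise ValueError(f"at_day must be >= 0, got {at_day}")
    if mode == "model":
        predicted = remaining_fraction(fit.a_hat, fit.k_hat, at_day)
    elif mode == "observation":
        if ts is None:
            raise ValueError("observation mode requires the time series")
        predicted = float(ts.remaining[np.argmin(np.abs(ts.times - at_day))])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return mass_margin(predicted, fit.asymptote_hat)
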