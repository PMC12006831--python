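"""Validity auditing of TBI measurements and predicted-vs-observed comparison.

The TBI closed forms are only interpretable when their assumptions hold:
the rooibos bag must still be well above its asymptote (mass margin above
a threshold, 10% of initial dry mass by default), the incubation must fall
in the recommended 45-135 day window, and the green-tea stabilisation
factor must be non-negative. This module flags violations, filters
cohorts, fits the asymptote-transfer regression between green tea and
rooibos, produces the three candidate k predictions (S-derived asymptote,
observed fitted asymptote, transferred asymptote), and summarises how
predicted rates compare with rates observed in time series — overall and
stratified by mass-margin bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import (
    DEFAULT_MM_THRESHOLD_PCT,
    DEFAULT_WINDOW_DAYS,
    AsymptoteReachedError,
    Flag,
    HarvestRecord,
    TBIConstants,
    TBIResult,
    k_from_asymptote,
    tbi_from_pair,
)
from .fitting import DecayFit

__all__ = [
    "ValidityReport",
    "TransferModel",
    "KVariants",
    "BinStats",
    "ComparisonSummary",
    "DEFAULT_MM_BINS_PCT",
    "audit_pair",
    "filter_usable",
    "fit_transfer",
    "predict_k_variants",
    "compare_predicted_observed",
]

#: Mass-margin bin edges (%) separating unreliable, marginal and safe pairs.
DEFAULT_MM_BINS_PCT = (5.0, 10.0)

_BLOCKING_FLAGS = frozenset(
    {Flag.NEGATIVE_S, Flag.LOW_MASS_MARGIN, Flag.OUT_OF_WINDOW, Flag.ASYMPTOTE_REACHED}
)


@dataclass(frozen=True)
class ValidityReport:
    """Audit outcome for one pair; usable means no blocking flag raised."""

    id: str
    flags: frozenset[Flag]
    mm_rooibos_pct: float
    mm_green_pct: float | None = None
    usable: bool = field(default=False)


@dataclass(frozen=True)
class TransferModel:
    """OLS regression of the rooibos asymptote on the green-tea asymptote."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    n: int

    def predict(self, green_asymptote: float) -> float:
        return self.intercept + self.slope * green_asymptote


@dataclass(frozen=True)
class KVariants:
    """The three candidate rooibos rate predictions for one pair.

    Each variant inverts the observed rooibos mass loss with a different
    asymptote source; a variant whose asymptote is already reached is None
    and listed in ``undefined``.
    """

    k_tbi: float | None
    k_from_observed_asymptote: float | None
    k_from_transferred_asymptote: float | None
    undefined: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class BinStats:
    n: int
    bias: float
    rmse: float


@dataclass(frozen=True)
class ComparisonSummary:
    """Predicted-vs-observed k agreement, overall and per mass-margin bin."""

    n_pairs: int
    rmse: float
    bias: float
    slope: float
    intercept: float
    bins: dict[str, BinStats]


def audit_pair(
    result: TBIResult,
    *,
    window_days: tuple[float, float] = DEFAULT_WINDOW_DAYS,
    mm_threshold_pct: float = DEFAULT_MM_THRESHOLD_PCT,
    strict_green: bool = False,
) -> ValidityReport:
    """Re-derive validity flags for a TBI result under explicit thresholds.

    Flags are recomputed from the numeric fields so the same result can be
    audited under different windows/thresholds; MASS_GAIN (not derivable
    from the summary numbers) is carried over from the result. In
    ``strict_green`` mode a green mass margin of magnitude above 5% also
    blocks usability (by default the green margin is reported only).
    """
    flags: set[Flag] = set()
    if result.s_tbi < 0:
        flags.add(Flag.NEGATIVE_S)
    if result.k_tbi is None or result.mm_rooibos_pct <= 0:
        flags.add(Flag.ASYMPTOTE_REACHED)
    if result.mm_rooibos_pct <= mm_threshold_pct:
        flags.add(Flag.LOW_MASS_MARGIN)
    if not window_days[0] <= result.incubation_days <= window_days[1]:
        flags.add(Flag.OUT_OF_WINDOW)
    if Flag.MASS_GAIN in result.flags:
        flags.add(Flag.MASS_GAIN)

    usable = not (flags & _BLOCKING_FLAGS)
    if strict_green and result.mm_green_pct is not None:
        usable = usable and abs(result.mm_green_pct) <= 5.0

    return ValidityReport(
        id=result.id,
        flags=frozenset(flags),
        mm_rooibos_pct=result.mm_rooibos_pct,
        mm_green_pct=result.mm_green_pct,
        usable=usable,
    )


def filter_usable(
    reports: list[ValidityReport],
) -> tuple[list[ValidityReport], float]:
    """Usable subset and the retention fraction in percent."""
    if not reports:
        raise ValueError("cannot filter an empty collection of reports")
    usable = [r for r in reports if r.usable]
    return usable, 100.0 * len(usable) / len(reports)


def fit_transfer(
    green_asymptotes: "np.ndarray | list[float]",
    rooibos_asymptotes: "np.ndarray | list[float]",
) -> TransferModel:
    """OLS of the rooibos asymptote on the green asymptote (both as
    remaining-mass fractions).

    This is the empirical relationship that lets a green-tea harvest stand
    in for the rooibos asymptote. Reports slope, intercept, R^2 and the F
    statistic on (1, n-2) degrees of freedom.
    """
    x = np.asarray(green_asymptotes, dtype=float)
    y = np.asarray(rooibos_asymptotes, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D inputs with n >= 3")
    if float(np.var(x)) == 0.0:
        raise ValueError("zero variance in the green asymptotes; slope undefined")
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(ols.rsquared)
    n = int(x.size)
    # F from the R^2 identity: exact for simple regression and finite even
    # when the fit is perfect only up to rounding.
    f = math.inf if r2 >= 1.0 else r2 * (n - 2) / (1.0 - r2)
    return TransferModel(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        r_squared=r2,
        f_statistic=f,
        df_num=1,
        df_den=n - 2,
        n=n,
    )


def _invert(remaining: float, asymptote: float, t: float) -> float | None:
    if not 0.0 < asymptote < 1.0:
        return None
    if remaining >= 1.0:
        return 0.0
    try:
        return k_from_asymptote(remaining, asymptote, t)
    except AsymptoteReachedError:
        return None


def predict_k_variants(
    green: HarvestRecord,
    rooibos: HarvestRecord,
    rooibos_fit: DecayFit,
    transfer: TransferModel,
    constants: TBIConstants = TBIConstants(),
) -> KVariants:
    """Three rooibos rate predictions from one pair.

    * ``k_tbi`` — asymptote derived from the green-tea stabilisation factor
      (the standard TBI chain);
    * ``k_from_observed_asymptote`` — asymptote taken from the fitted
      rooibos time series (``rooibos_fit.asymptote_hat``);
    * ``k_from_transferred_asymptote`` — asymptote predicted from the green
      remaining fraction through the transfer regression.

    Variants whose asymptote is at or above the observed remaining mass are
    None and named in ``undefined`` — they are flagged, never dropped
    silently.
    """
    result = tbi_from_pair(green, rooibos, constants, day_tolerance=math.inf)
    remaining = rooibos.remaining_fraction
    day = rooibos.incubation_days

    variants = {
        "k_tbi": result.k_tbi,
        "k_from_observed_asymptote": _invert(remaining, rooibos_fit.asymptote_hat, day),
        "k_from_transferred_asymptote": _invert(
            remaining, transfer.predict(green.remaining_fraction), day
        ),
    }
    undefined = frozenset(name for name, k in variants.items() if k is None)
    return KVariants(**variants, undefined=undefined)


def _bin_label(mm: float, edges: tuple[float, float]) -> str:
    lo, hi = edges
    if mm <= lo:
        return f"<= {lo:g}%"
    if mm <= hi:
        return f"{lo:g}-{hi:g}%"
    return f"> {hi:g}%"


def compare_predicted_observed(
    pairs: list[tuple[float, float, float]],
    *,
    mm_bins_pct: tuple[float, float] = DEFAULT_MM_BINS_PCT,
) -> ComparisonSummary:
    """Summarise (k_predicted, k_observed, mass margin %) triples.

    Reports RMSE and mean bias (predicted - observed), the OLS line of
    predicted on observed, and bias/RMSE within mass-margin bins. The bins
    make the margin-dependence of the prediction error visible: pairs close
    to their asymptote are where the TBI inversion degrades.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    arr = np.asarray(pairs, dtype=float)
    pred, obs, mm = arr[:, 0], arr[:, 1], arr[:, 2]
    diff = pred - obs
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))

    if float(np.var(obs)) == 0.0:
        slope, intercept = math.nan, math.nan
    else:
        ols = sm.OLS(pred, sm.add_constant(obs)).fit()
        slope, intercept = float(ols.params[1]), float(ols.params[0])

    bins: dict[str, BinStats] = {}
    labels = [_bin_label(m, mm_bins_pct) for m in mm]
    for label in (
        f"<= {mm_bins_pct[0]:g}%",
        f"{mm_bins_pct[0]:g}-{mm_bins_pct[1]:g}%",
        f"> {mm_bins_pct[1]:g}%",
    ):
        mask = np.array([l == label for l in labels])
        if np.any(mask):
            d = diff[mask]
            bins[label] = BinStats(
                n=int(mask.sum()),
                bias=float(np.mean(d)),
                rmse=float(np.sqrt(np.mean(d**2))),
            )
        else:
            bins[label] = BinStats(n=0, bias=math.nan, rmse=math.nan)

    return ComparisonSummary(
        n_pairs=len(pairs), rmse=rmse, bias=bias, slope=slope, intercept=intercept, bins=bins
    )
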