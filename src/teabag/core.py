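"""Closed-form Tea Bag Index (TBI) mathematics.

The TBI evaluates paired 90-day incubations of green tea (fast decomposing)
and rooibos (slow decomposing) with a two-pool asymptotic exponential model

    m(t) = a * exp(-k * t) + (1 - a)

where ``a`` is the decomposable (labile) fraction and ``1 - a`` the
asymptote. Green-tea mass loss, scaled by its hydrolysable fraction, gives
the stabilisation factor ``S``; ``S`` is transferred to rooibos to obtain
its decomposable fraction, and the observed rooibos mass loss is inverted
for the initial decomposition rate ``k``. The mass margin — the distance of
the observed remaining mass above the modelled asymptote, in percent of
initial dry mass — quantifies whether a bag is still far enough from its
asymptote for the inversion to be meaningful.

All rates are per day, all masses are fractions of the initial dry mass
unless a field name says otherwise, and negative or out-of-range values are
flagged rather than clamped so that data problems stay visible downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "TeaType",
    "Flag",
    "TBIConstants",
    "HarvestRecord",
    "TBIResult",
    "AsymptoteReachedError",
    "PairingError",
    "DEFAULT_MM_THRESHOLD_PCT",
    "DEFAULT_WINDOW_DAYS",
    "remaining_fraction",
    "stabilisation_factor",
    "decomposable_fraction_rooibos",
    "k_from_asymptote",
    "mass_margin",
    "tbi_from_pair",
]

#: Rooibos mass-margin validity threshold, percent of initial dry mass.
DEFAULT_MM_THRESHOLD_PCT = 10.0
#: Recommended incubation-duration window, days.
DEFAULT_WINDOW_DAYS = (45.0, 135.0)


class TeaType(str, Enum):
    GREEN = "green"
    ROOIBOS = "rooibos"

    @classmethod
    def parse(cls, value: object) -> "TeaType":
        """Normalise free-text labels ('Green ', 'ROOIBOS') to a TeaType."""
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())


class Flag(str, Enum):
    """Validity-flag codes attached to TBI results and audit reports."""

    NEGATIVE_S = "NEGATIVE_S"
    ASYMPTOTE_REACHED = "ASYMPTOTE_REACHED"
    LOW_MASS_MARGIN = "LOW_MASS_MARGIN"
    OUT_OF_WINDOW = "OUT_OF_WINDOW"
    MASS_GAIN = "MASS_GAIN"


class AsymptoteReachedError(ValueError):
    """The observed remaining mass is at or below the modelled asymptote.

    The rate inversion is undefined there; the offending mass margin (in
    percent of initial dry mass) is carried on the exception.
    """

    def __init__(self, margin_pct: float):
        self.margin_pct = margin_pct
        super().__init__(
            f"remaining mass at/below asymptote (mass margin {margin_pct:.2f}%); "
            "k is undefined"
        )


class PairingError(ValueError):
    """Green/rooibos records cannot form a valid TBI pair."""


@dataclass(frozen=True)
class TBIConstants:
    """Hydrolysable mass fractions of the two standard teas (g/g).

    Defaults follow the original TBI parameterisation; alternative chemical
    parameterisations can be supplied, which is why these are configuration
    values and never appear inline in the formulas.
    """

    h_green: float = 0.842
    h_rooibos: float = 0.552

    def __post_init__(self) -> None:
        for name, h in (("h_green", self.h_green), ("h_rooibos", self.h_rooibos)):
            if not 0.0 < h <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {h}")


@dataclass(frozen=True)
class HarvestRecord:
    """One tea bag's initial/final dry mass and incubation duration."""

    id: str
    tea_type: TeaType
    initial_mass_g: float
    final_mass_g: float
    incubation_days: float
    pair_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tea_type", TeaType.parse(self.tea_type))
        if self.initial_mass_g <= 0:
            raise ValueError(f"initial_mass_g must be > 0, got {self.initial_mass_g}")
        if self.final_mass_g < 0:
            raise ValueError(f"final_mass_g must be >= 0, got {self.final_mass_g}")
        if self.incubation_days <= 0:
            raise ValueError(
                f"incubation_days must be > 0, got {self.incubation_days}"
            )

    @property
    def remaining_fraction(self) -> float:
        return self.final_mass_g / self.initial_mass_g

    @property
    def has_mass_gain(self) -> bool:
        """Remaining fraction above 1 — permitted but a data-quality flag."""
        return self.remaining_fraction > 1.0


@dataclass(frozen=True)
class TBIResult:
    """TBI parameters and validity flags for one green/rooibos pair.

    ``k_tbi`` is ``None`` (never NaN) when the rooibos bag is at or past
    its modelled asymptote; ``mm_green`` is ``None`` at pair level because
    the S-derived green asymptote coincides with the observed green mass by
    construction (a green margin needs a fitted time series).
    """

    id: str
    s_tbi: float
    a_green: float
    a_rooibos: float
    k_tbi: float | None
    mm_rooibos_pct: float
    incubation_days: float
    flags: frozenset[Flag] = field(default_factory=frozenset)
    mm_green_pct: float | None = None


def remaining_fraction(a: float, k: float, t: float) -> float:
    """Two-pool decay curve m(t) = a*exp(-k t) + (1 - a).

    Parameters are the decomposable fraction ``a`` in [0, 1], rate ``k``
    (day^-1, >= 0) and time ``t`` (days, >= 0); accepts numpy arrays for
    any argument. The value lies in [1 - a, 1].
    """
    a_arr, k_arr, t_arr = np.asarray(a), np.asarray(k), np.asarray(t)
    if np.any(a_arr < 0) or np.any(a_arr > 1):
        raise ValueError("decomposable fraction a must be in [0, 1]")
    if np.any(k_arr < 0):
        raise ValueError("rate k must be >= 0")
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = a_arr * np.exp(-k_arr * t_arr) + (1.0 - a_arr)
    return float(out) if out.ndim == 0 else out


def stabilisation_factor(
    loss_fraction_green: float, constants: TBIConstants = TBIConstants()
) -> float:
    """Stabilisation factor S = 1 - loss_green / H_green.

    ``loss_fraction_green`` is the decomposed mass fraction of green tea at
    harvest, in [0, 1]. S may be negative (more mass lost than the
    hydrolysable pool holds); callers must flag, not clamp.
    """
    if not 0.0 <= loss_fraction_green <= 1.0:
        raise ValueError(
            f"green-tea loss fraction must be in [0, 1], got {loss_fraction_green}"
        )
    return 1.0 - loss_fraction_green / constants.h_green


def decomposable_fraction_rooibos(
    s: float, constants: TBIConstants = TBIConstants()
) -> float:
    """Rooibos decomposable fraction a_r = H_rooibos * (1 - S).

    For S in [0, 1] the result lies in [0, H_rooibos]; for S < 0 it exceeds
    H_rooibos and the caller must propagate the NEGATIVE_S flag.
    """
    if s > 1.0:
        raise ValueError(f"stabilisation factor must be <= 1, got {s}")
    return constants.h_rooibos * (1.0 - s)


def k_from_asymptote(remaining: float, asymptote: float, t: float) -> float:
    """Invert the two-pool curve for the rate: k = ln(a/(m - A)) / t.

    ``remaining`` is the observed remaining mass fraction at day ``t`` and
    ``asymptote`` the modelled limit A = 1 - a. Exact inverse of
    :func:`remaining_fraction`. Raises :class:`AsymptoteReachedError` when
    the bag is at or below its asymptote (mass margin <= 0); returns 0.0 at
    the no-loss boundary remaining = 1.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if not 0.0 < asymptote < 1.0:
        raise ValueError(f"asymptote must be in (0, 1), got {asymptote}")
    if remaining > 1.0:
        raise ValueError(f"remaining fraction must be <= 1, got {remaining}")
    if remaining <= asymptote:
        raise AsymptoteReachedError(mass_margin(remaining, asymptote))
    a = 1.0 - asymptote
    return math.log(a / (remaining - asymptote)) / t


def mass_margin(remaining: float, asymptote: float) -> float:
    """Mass margin MM = 100 * (remaining - asymptote), % of initial dry mass.

    Positive means the bag has not yet reached its modelled asymptote;
    negative values (observed mass below the asymptote) are returned as-is.
    """
    for name, x in (("remaining", remaining), ("asymptote", asymptote)):
        if not 0.0 <= x <= 1.2:
            raise ValueError(f"{name} fraction outside plausible [0, 1.2]: {x}")
    return 100.0 * (remaining - asymptote)


def tbi_from_pair(
    green: HarvestRecord,
    rooibos: HarvestRecord,
    constants: TBIConstants = TBIConstants(),
    *,
    day_tolerance: float = 0.0,
    mm_threshold_pct: float = DEFAULT_MM_THRESHOLD_PCT,
    window_days: tuple[float, float] = DEFAULT_WINDOW_DAYS,
) -> TBIResult:
    """Full TBI chain for one harvest pair, flagging instead of raising.

    Chains stabilisation factor -> rooibos decomposable fraction -> rate
    inversion -> mass margin. Sets NEGATIVE_S, ASYMPTOTE_REACHED (k then
    reported as None), LOW_MASS_MARGIN (mm_rooibos <= threshold),
    OUT_OF_WINDOW (incubation outside ``window_days``) and MASS_GAIN
    (remaining > 1 in either bag). A green bag that gained mass is treated
    as zero loss (S = 1) so the S <= 1 invariant holds; a rooibos bag that
    gained mass gets the k = 0 no-loss boundary. Raises
    :class:`PairingError` on mismatched tea types or incubation days
    differing by more than ``day_tolerance``.
    """
    if green.tea_type is not TeaType.GREEN or rooibos.tea_type is not TeaType.ROOIBOS:
        raise PairingError(
            f"expected (green, rooibos) pair, got ({green.tea_type.value}, "
            f"{rooibos.tea_type.value})"
        )
    if abs(green.incubation_days - rooibos.incubation_days) > day_tolerance:
        raise PairingError(
            f"incubation days differ by more than {day_tolerance} d: "
            f"{green.incubation_days} vs {rooibos.incubation_days}"
        )

    flags: set[Flag] = set()
    green_remaining = green.remaining_fraction
    rooibos_remaining = rooibos.remaining_fraction

    if green_remaining > 1.0:
        flags.add(Flag.MASS_GAIN)
        green_loss = 0.0
    else:
        green_loss = 1.0 - green_remaining
    if rooibos_remaining > 1.0:
        flags.add(Flag.MASS_GAIN)

    s = stabilisation_factor(green_loss, constants)
    if s < 0:
        flags.add(Flag.NEGATIVE_S)
    a_r = decomposable_fraction_rooibos(s, constants)
    asymptote_r = 1.0 - a_r

    day = rooibos.incubation_days
    mm_r = mass_margin(rooibos_remaining, asymptote_r)

    k: float | None
    if rooibos_remaining >= 1.0:
        k = 0.0  # no net mass loss: boundary of the inversion
    elif a_r <= 0 or not 0.0 < asymptote_r < 1.0:
        # degenerate transfer (S = 1 or S so negative that a_r >= 1)
        flags.add(Flag.ASYMPTOTE_REACHED)
        k = None
    else:
        try:
            k = k_from_asymptote(rooibos_remaining, asymptote_r, day)
        except AsymptoteReachedError:
            flags.add(Flag.ASYMPTOTE_REACHED)
            k = None

    if mm_r <= mm_threshold_pct:
        flags.add(Flag.LOW_MASS_MARGIN)
    if not window_days[0] <= day <= window_days[1]:
        flags.add(Flag.OUT_OF_WINDOW)

    return TBIResult(
        id=green.pair_id or rooibos.pair_id or f"{green.id}+{rooibos.id}",
        s_tbi=s,
        a_green=green_loss,
        a_rooibos=a_r,
        k_tbi=k,
        mm_rooibos_pct=mm_r,
        incubation_days=day,
        flags=frozenset(flags),
    )
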