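"""Synthetic decomposition curves and harvests with controllable violations.

The forward model is the three-fraction view of a litter bag: a labile
pool that decays at rate ``k_labile``, a stabilised pool that is inert on
the incubation timescale, and a recalcitrant pool that is nominally inert
(``k_recalcitrant = 0``) but can be made to leak slowly — the assumption
violation that inflates short-series rate and asymptote estimates:

    remaining(t) = a_labile * exp(-k_labile * t)
                 + s_stabilised
                 + r_recalcitrant * exp(-k_recalcitrant * t)
                 + noise,   noise ~ N(0, noise_sd^2) i.i.d.

With ``k_recalcitrant = 0`` this is exactly the two-pool TBI curve with
a = a_labile; with ``s = r = 0`` it is the pure single exponential. Noise
is additive Gaussian on the remaining fraction (a balance-error model),
truncated to (0, 1.2]; a day-0 observation is pinned to exactly 1 because
remaining mass is normalised to the initial mass. Everything is
reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import HarvestRecord, TeaType
from .fitting import TimeSeries, fit_decay

__all__ = [
    "LAB_DAYS",
    "SPARSE_DAYS",
    "ScenarioConfig",
    "two_pool_scenario",
    "noiseless_remaining",
    "generate_series",
    "generate_pair",
    "recovery_experiment",
    "standard_scenarios",
]

#: Lab-like weekly-to-biweekly sampling design.
LAB_DAYS = (7.0, 14.0, 21.0, 28.0, 42.0, 60.0, 75.0, 90.0)
#: Sparse monthly design with a long tail.
SPARSE_DAYS = (30.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated litter-bag scenario (pools, kinetics, noise, design)."""

    a_labile: float
    k_labile: float
    s_stabilised: float
    r_recalcitrant: float = 0.0
    k_recalcitrant: float = 0.0
    noise_sd: float = 0.0
    sampling_days: tuple[float, ...] = LAB_DAYS
    seed: int = 0
    tea_type: TeaType = TeaType.ROOIBOS
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tea_type", TeaType.parse(self.tea_type))
        object.__setattr__(self, "sampling_days", tuple(float(d) for d in self.sampling_days))
        fracs = (self.a_labile, self.s_stabilised, self.r_recalcitrant)
        if any(f < 0 for f in fracs):
            raise ValueError("pool fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"pool fractions must sum to 1, got {sum(fracs)}")
        if self.k_labile < 0 or self.k_recalcitrant < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be >= 0")
        days = self.sampling_days
        if len(days) < 1 or any(d < 0 for d in days) or any(
            b <= a for a, b in zip(days, days[1:])
        ):
            raise ValueError("sampling_days must be non-empty, >= 0, strictly increasing")


def two_pool_scenario(
    a: float, k: float, *, noise_sd: float = 0.0, sampling_days=LAB_DAYS,
    seed: int = 0, tea_type: TeaType = TeaType.ROOIBOS, name: str = "",
) -> ScenarioConfig:
    """TBI-conformant scenario: labile pool a, inert remainder 1 - a."""
    return ScenarioConfig(
        a_labile=a, k_labile=k, s_stabilised=1.0 - a, noise_sd=noise_sd,
        sampling_days=tuple(sampling_days), seed=seed, tea_type=tea_type, name=name,
    )


def noiseless_remaining(config: ScenarioConfig, t) -> np.ndarray:
    """Exact forward model evaluated at days ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    out = (
        config.a_labile * np.exp(-config.k_labile * t)
        + config.s_stabilised
        + config.r_recalcitrant * np.exp(-config.k_recalcitrant * t)
    )
    return float(out) if out.ndim == 0 else out


def _noisy_draw(curve: np.ndarray, days: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    y = curve + rng.normal(0.0, noise_sd, size=curve.shape) if noise_sd > 0 else curve.copy()
    y = np.clip(y, 1e-9, 1.2)
    y[days == 0] = 1.0  # normalised to initial mass by definition
    return y


def generate_series(config: ScenarioConfig, series_id: str | None = None) -> TimeSeries:
    """One noisy realisation of the scenario as a TimeSeries."""
    days = np.asarray(config.sampling_days, dtype=float)
    rng = np.random.default_rng(config.seed)
    y = _noisy_draw(noiseless_remaining(config, days), days, config.noise_sd, rng)
    return TimeSeries(
        id=series_id or config.name or f"sim-{config.seed}",
        tea_type=config.tea_type,
        times=days,
        remaining=y,
    )


def generate_pair(
    scenario_green: ScenarioConfig,
    scenario_rooibos: ScenarioConfig,
    harvest_day: float,
    seed: int,
    *,
    initial_mass_g: float = 2.0,
    pair_id: str | None = None,
) -> tuple[HarvestRecord, HarvestRecord]:
    """Single-harvest green/rooibos records: one noisy draw of each forward
    model at ``harvest_day`` (day 0 draws are exactly 1)."""
    rng = np.random.default_rng(seed)
    day = np.asarray([float(harvest_day)])
    records = []
    for scenario, tea in (
        (scenario_green, TeaType.GREEN),
        (scenario_rooibos, TeaType.ROOIBOS),
    ):
        y = _noisy_draw(noiseless_remaining(scenario, day), day, scenario.noise_sd, rng)
        label = pair_id or f"pair-{seed}"
        records.append(
            HarvestRecord(
                id=f"{label}-{tea.value}",
                tea_type=tea,
                initial_mass_g=initial_mass_g,
                final_mass_g=initial_mass_g * float(y[0]),
                incubation_days=float(harvest_day) if harvest_day > 0 else 1e-9,
                pair_id=label,
            )
        )
    return records[0], records[1]


def recovery_experiment(
    grid: Sequence[ScenarioConfig], n_reps: int, base_seed: int
) -> pd.DataFrame:
    """Monte-Carlo parameter recovery over a scenario grid.

    For each scenario, ``n_reps`` series are generated with seeds
    ``base_seed .. base_seed + n_reps - 1`` and fitted; rows report the
    bias and RMSE of k_hat, the bias of the asymptote, and the success
    rate (bias/RMSE over successful fits). Deterministic given base_seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rows = []
    for i, scenario in enumerate(grid):
        true_k = scenario.k_labile
        true_asym = 1.0 - scenario.a_labile  # asymptote of the nested two-pool model
        k_hats, asym_hats, n_success = [], [], 0
        for j in range(n_reps):
            fit = fit_decay(
                generate_series(replace(scenario, seed=base_seed + j), series_id=f"s{i}r{j}")
            )
            if fit.success:
                n_success += 1
                k_hats.append(fit.k_hat)
                asym_hats.append(fit.asymptote_hat)
        k_arr, a_arr = np.asarray(k_hats), np.asarray(asym_hats)
        rows.append(
            {
                "scenario": scenario.name or f"scenario-{i}",
                "k_true": true_k,
                "n_reps": n_reps,
                "success_rate": n_success / n_reps,
                "bias_k": float(np.mean(k_arr - true_k)) if k_arr.size else np.nan,
                "rmse_k": float(np.sqrt(np.mean((k_arr - true_k) ** 2))) if k_arr.size else np.nan,
                "bias_asymptote": float(np.mean(a_arr - true_asym)) if a_arr.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def standard_scenarios() -> dict[str, ScenarioConfig]:
    """Twelve named scenarios spanning conformant, noisy and violating cases."""
    s = {
        "green_conformant": ScenarioConfig(0.7, 0.08, 0.158, 0.142, 0.0, 0.0, LAB_DAYS, 1, TeaType.GREEN),
        "green_noisy": ScenarioConfig(0.7, 0.08, 0.158, 0.142, 0.0, 0.01, LAB_DAYS, 2, TeaType.GREEN),
        "rooibos_conformant": ScenarioConfig(0.4416, 0.0093, 0.1104, 0.448, 0.0, 0.0, LAB_DAYS, 3),
        "rooibos_noisy": ScenarioConfig(0.4416, 0.0093, 0.1104, 0.448, 0.0, 0.005, LAB_DAYS, 4),
        "rooibos_noisier": ScenarioConfig(0.4416, 0.0093, 0.1104, 0.448, 0.0, 0.02, LAB_DAYS, 5),
        "rooibos_fast": ScenarioConfig(0.45, 0.03, 0.55, 0.0, 0.0, 0.005, LAB_DAYS, 6),
        "rooibos_near_asymptote": ScenarioConfig(0.45, 0.08, 0.55, 0.0, 0.0, 0.005, LAB_DAYS, 7),
        "recalcitrant_leak": ScenarioConfig(0.3, 0.05, 0.4, 0.3, 0.002, 0.0, tuple(range(5, 125, 5)), 8),
        "recalcitrant_leak_noisy": ScenarioConfig(0.3, 0.05, 0.4, 0.3, 0.002, 0.005, tuple(range(5, 125, 5)), 9),
        "sparse_design": ScenarioConfig(0.4416, 0.0093, 0.5584, 0.0, 0.0, 0.005, SPARSE_DAYS, 10),
        "single_pool": ScenarioConfig(1.0, 0.01, 0.0, 0.0, 0.0, 0.0, LAB_DAYS, 11),
        "slow_decay": ScenarioConfig(0.4, 0.002, 0.6, 0.0, 0.0, 0.005, SPARSE_DAYS, 12),
    }
    return {name: replace(cfg, name=name) for name, cfg in s.items()}
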