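"""CSV and config plumbing for harvest tables, time series and reports.

One strict dialect everywhere: comma separator, '.' decimal, UTF-8, LF,
header row required. Percentages are always serialised on the 0-100 scale
in columns suffixed ``_pct``. Malformed rows are reported with their line
number; a hard violation aborts unless ``skip_bad`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_MM_THRESHOLD_PCT,
    DEFAULT_WINDOW_DAYS,
    HarvestRecord,
    TBIConstants,
    TBIResult,
    TeaType,
)
from .diagnostics import DEFAULT_MM_BINS_PCT, ValidityReport
from .fitting import DecayFit, TimeSeries

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_config",
    "read_harvest_table",
    "write_harvest_table",
    "read_timeseries_table",
    "write_timeseries_table",
    "write_fit_table",
    "write_audit_table",
    "write_result_table",
    "read_result_table",
]

HARVEST_COLUMNS = ["id", "tea_type", "initial_mass_g", "final_mass_g", "incubation_days", "pair_id"]
SERIES_COLUMNS = ["id", "tea_type", "day", "remaining_fraction"]


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, constants and seed governing one pipeline run."""

    constants: TBIConstants = field(default_factory=TBIConstants)
    mm_threshold_pct: float = DEFAULT_MM_THRESHOLD_PCT
    window_days: tuple[float, float] = DEFAULT_WINDOW_DAYS
    mm_bins_pct: tuple[float, float] = DEFAULT_MM_BINS_PCT
    day_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mm_threshold_pct <= 0:
            raise ValueError("mm_threshold_pct must be positive")
        if not self.window_days[0] < self.window_days[1]:
            raise ValueError("window min must be below window max")


_CONFIG_KEYS = {
    "h_green",
    "h_rooibos",
    "mm_threshold_pct",
    "window_min_days",
    "window_max_days",
    "day_tolerance",
    "seed",
}


def read_config(path: str | Path) -> RunConfig:
    """Parse a key=value text config (``#`` starts a comment)."""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip().lower()
        if key not in _CONFIG_KEYS:
            raise SchemaError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            values[key] = float(val.strip())
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-numeric value {val.strip()!r}") from exc
    return RunConfig(
        constants=TBIConstants(
            h_green=values.get("h_green", TBIConstants().h_green),
            h_rooibos=values.get("h_rooibos", TBIConstants().h_rooibos),
        ),
        mm_threshold_pct=values.get("mm_threshold_pct", DEFAULT_MM_THRESHOLD_PCT),
        window_days=(
            values.get("window_min_days", DEFAULT_WINDOW_DAYS[0]),
            values.get("window_max_days", DEFAULT_WINDOW_DAYS[1]),
        ),
        day_tolerance=values.get("day_tolerance", 0.0),
        seed=int(values.get("seed", 0)),
    )


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_harvest_table(path: str | Path, *, skip_bad: bool = False) -> list[HarvestRecord]:
    """Read harvest records; tea-type labels are case/space normalised."""
    df = pd.read_csv(path, dtype={"id": str, "pair_id": str})
    _require_columns(df, [c for c in HARVEST_COLUMNS if c != "pair_id"], path)
    records: list[HarvestRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            records.append(
                HarvestRecord(
                    id=str(row["id"]),
                    tea_type=TeaType.parse(row["tea_type"]),
                    initial_mass_g=float(row["initial_mass_g"]),
                    final_mass_g=float(row["final_mass_g"]),
                    incubation_days=float(row["incubation_days"]),
                    pair_id=(
                        str(row["pair_id"])
                        if "pair_id" in df.columns and pd.notna(row.get("pair_id"))
                        else None
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"{path}:{lineno}: {exc}")
    if errors and not skip_bad:
        raise SchemaError("; ".join(errors))
    return records


def write_harvest_table(records: list[HarvestRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "tea_type": [r.tea_type.value for r in records],
            "initial_mass_g": [r.initial_mass_g for r in records],
            "final_mass_g": [r.final_mass_g for r in records],
            "incubation_days": [r.incubation_days for r in records],
            "pair_id": [r.pair_id or "" for r in records],
        }
    ).to_csv(path, index=False, lineterminator="\n")


def read_timeseries_table(path: str | Path) -> list[TimeSeries]:
    """Read long-format series (one row per observation), grouped by id."""
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, SERIES_COLUMNS, path)
    out = []
    for sid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("day")
        tea = grp["tea_type"].iloc[0]
        out.append(
            TimeSeries(
                id=str(sid),
                tea_type=TeaType.parse(tea),
                times=grp["day"].to_numpy(dtype=float),
                remaining=grp["remaining_fraction"].to_numpy(dtype=float),
            )
        )
    return out


def write_timeseries_table(series: list[TimeSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "id": ts.id,
                "tea_type": ts.tea_type.value,
                "day": ts.times,
                "remaining_fraction": ts.remaining,
            }
        )
        for ts in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\n")


def write_fit_table(fits: list[DecayFit], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [f.id for f in fits],
            "a_hat": [f.a_hat for f in fits],
            "k_hat": [f.k_hat for f in fits],
            "asymptote_hat": [f.asymptote_hat for f in fits],
            "rss": [f.rss for f in fits],
            "n_points": [f.n_points for f in fits],
            "converged": [f.converged for f in fits],
            "success": [f.success for f in fits],
            "max_day": [f.max_day for f in fits],
            "reason": [f.reason or "" for f in fits],
        }
    ).to_csv(path, index=False, lineterminator="\n")


def write_result_table(results: list[TBIResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in results],
            "s_tbi": [r.s_tbi for r in results],
            "a_green": [r.a_green for r in results],
            "a_rooibos": [r.a_rooibos for r in results],
            "k_tbi": [r.k_tbi if r.k_tbi is not None else np.nan for r in results],
            "mm_rooibos_pct": [r.mm_rooibos_pct for r in results],
            "incubation_days": [r.incubation_days for r in results],
            "flags": [";".join(sorted(f.value for f in r.flags)) for r in results],
        }
    ).to_csv(path, index=False, lineterminator="\n")


def read_result_table(path: str | Path) -> list[TBIResult]:
    from .core import Flag

    df = pd.read_csv(path, dtype={"id": str, "flags": str})
    _require_columns(df, ["id", "s_tbi", "k_tbi", "mm_rooibos_pct", "incubation_days"], path)
    out = []
    for _, row in df.iterrows():
        flags = frozenset(
            Flag(f) for f in str(row.get("flags", "")).split(";") if f and f != "nan"
        )
        k = float(row["k_tbi"])
        out.append(
            TBIResult(
                id=str(row["id"]),
                s_tbi=float(row["s_tbi"]),
                a_green=float(row.get("a_green", np.nan)),
                a_rooibos=float(row.get("a_rooibos", np.nan)),
                k_tbi=None if np.isnan(k) else k,
                mm_rooibos_pct=float(row["mm_rooibos_pct"]),
                incubation_days=float(row["incubation_days"]),
                flags=flags,
            )
        )
    return out


def write_audit_table(reports: list[ValidityReport], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in reports],
            "flags": [";".join(sorted(f.value for f in r.flags)) for r in reports],
            "mm_green_pct": [
                r.mm_green_pct if r.mm_green_pct is not None else np.nan for r in reports
            ],
            "mm_rooibos_pct": [r.mm_rooibos_pct for r in reports],
            "usable": [r.usable for r in reports],
        }
    ).to_csv(path, index=False, lineterminator="\n")
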