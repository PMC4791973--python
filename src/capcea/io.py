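"""File formats, configuration and summary tables.

Event histories travel as plain CSV with the columns ``subject_id,
stratum, arm, origin_state, dest_state, entry_day, exit_day, status``
followed by one 0/1 column per covariate; ``dest_state`` is empty on
censored rows.  Run configuration is a single YAML (or JSON) document
whose defaults mirror the published analysis: horizon 14 days, 10,000 PSA
iterations, willingness to pay $0-$1000 per quality-adjusted life day in
20 intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from .synthetic_cohort import EVENT_COLUMNS, validate_event_history

__all__ = [
    "read_event_history",
    "write_event_history",
    "read_price_table",
    "summarize_regimens",
    "wtp_per_qaly",
    "RunConfig",
    "load_config",
]

DAYS_PER_YEAR = 365


def read_event_history(path) -> pd.DataFrame:
    """Read and validate an event-history CSV.

    All row-level problems are collected and reported together in a
    single ``ValueError``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["dest_state"] = df["dest_state"].astype("Int64")
    problems = validate_event_history(df)
    if problems:
        raise ValueError(f"{path}: invalid event history:\n" + "\n".join(problems))
    return df


def write_event_history(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_price_table(path) -> pd.DataFrame:
    """Read a drug price table CSV: regimen, iv_daily_usd, oral_daily_usd."""
    df = pd.read_csv(path)
    needed = ["regimen", "iv_daily_usd", "oral_daily_usd"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_regimens(events: pd.DataFrame) -> pd.DataFrame:
    """Patient counts and integer percentages per stratum and arm.

    Percentages are rounded half-up within each stratum.  Accepts either
    an event history (one row per sojourn) or any table with one row per
    patient carrying ``subject_id, stratum, arm``.
    """
    if events.empty:
        warnings.warn("empty input; regimen summary is empty")
        return pd.DataFrame(columns=["stratum", "arm", "n", "percent"])
    patients = events.drop_duplicates("subject_id")
    rows = []
    for stratum, grp in patients.groupby("stratum", sort=False):
        total = len(grp)
        for arm, sub in grp.groupby("arm", sort=False):
            rows.append(
                dict(
                    stratum=stratum,
                    arm=arm,
                    n=len(sub),
                    percent=_round_half_up(100.0 * len(sub) / total),
                )
            )
    return pd.DataFrame(rows)


def wtp_per_qaly(daily_wtp: float) -> float:
    """Convert $/quality-adjusted life day to $/QALY (365 days per year)."""
    if daily_wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return daily_wtp * DAYS_PER_YEAR


@dataclass
class RunConfig:
    """End-to-end run configuration with published defaults."""

    ward_total: int = 1438
    icu_total: int = 197
    frac_stable_at_admission: float = 0.02
    censor_day: int = 30
    event_history: Optional[str] = None  # path; generated if absent
    covariates: bool = True
    estimator: str = "nonparametric"  # or 'parametric'
    horizon: int = 14
    wtp_max: float = 1000.0
    wtp_intervals: int = 20
    psa_iterations: int = 10_000
    microsim_patients: int = 10_000
    seed: int = 0
    costs: Dict = field(default_factory=dict)  # optional overrides
    utilities: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimator not in ("nonparametric", "parametric"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not 1 <= self.horizon <= 30:
            raise ValueError("horizon must be in [1, 30]")
        if self.event_history is not None and not Path(self.event_history).exists():
            raise ValueError(f"event history file not found: {self.event_history}")


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration; absent keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = raw.pop("cohort", {})
    known = {
        k: v
        for k, v in {**cohort, **raw}.items()
        if k in RunConfig.__dataclass_fields__
    }
    unknown = set(raw) | set(cohort) - set(known)
    unknown -= set(RunConfig.__dataclass_fields__)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    return RunConfig(**known)
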