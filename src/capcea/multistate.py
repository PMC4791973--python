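"""Nonparametric multi-state estimation on a daily grid.

Cause-specific transition hazards are estimated as the number of observed
i -> j transitions on day t divided by the number of subjects occupying
state i just prior to t (day t is the interval (t-1, t]).  State-occupation
probabilities are the Aalen-Johansen product-integral of those hazard
increments; on a daily grid this is the same as multiplying daily
conditional transition matrices, so the two views are Chapman-Kolmogorov
consistent by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .states import ABSORBING_STATES, PERMITTED_TRANSITIONS, STATES

__all__ = [
    "CountingProcess",
    "DailyTransitionModel",
    "OccupationCurve",
    "counting_process",
    "aalen_johansen",
    "daily_transition_probabilities",
    "occupation_bootstrap_se",
    "transition_bootstrap_se",
]

_NSTATES = len(STATES)


@dataclass
class CountingProcess:
    """At-risk counts and transition counts per day.

    ``at_risk[i-1, t-1]`` is Y_i(t), the number of subjects in state i
    just prior to day t; ``transitions[(i, j)][t-1]`` is d_ij(t), the
    number of observed i -> j transitions on day t.
    """

    horizon: int
    at_risk: np.ndarray  # (4, horizon)
    transitions: Dict[Tuple[int, int], np.ndarray]

    def validate(self) -> None:
        for (i, j), d in self.transitions.items():
            if np.any(d > self.at_risk[i - 1]):
                raise ValueError(f"d_{i}{j}(t) exceeds Y_{i}(t) for some t")
        for i in (1, 2):
            total = sum(
                d for (o, _), d in self.transitions.items() if o == i
            )
            if np.any(np.asarray(total) > self.at_risk[i - 1]):
                raise ValueError(f"total transitions out of state {i} exceed Y_{i}(t)")


@dataclass
class DailyTransitionModel:
    """Daily conditional transition matrices with per-cell uncertainty.

    ``probs[t-1]`` is the 4x4 matrix of P(state j at t | state i at t-1);
    rows sum to one, absorbing rows are identity.  ``se`` holds per-cell
    standard errors (NaN where no uncertainty is attached, e.g. structural
    zeros and absorbing rows).  ``empty_risk_set[t-1, i-1]`` flags days on
    which no subject was at risk in state i and the identity row was
    emitted by convention.
    """

    horizon: int
    probs: np.ndarray  # (horizon, 4, 4)
    se: np.ndarray  # (horizon, 4, 4), NaN where absent
    provenance: str  # 'nonparametric' | 'parametric'
    stratum: Optional[str] = None
    arm: Optional[str] = None
    empty_risk_set: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.empty_risk_set is None:
            self.empty_risk_set = np.zeros((self.horizon, _NSTATES), dtype=bool)

    def validate(self) -> None:
        if not np.all((self.probs >= 0) & (self.probs <= 1)):
            raise ValueError("transition probabilities outside [0, 1]")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("transition-matrix rows must sum to 1")
        for s in ABSORBING_STATES:
            row = self.probs[:, s - 1, :]
            expect = np.zeros(_NSTATES)
            expect[s - 1] = 1.0
            if not np.allclose(row, expect, atol=0):
                raise ValueError(f"absorbing state {s} must have an identity row")
        for i in STATES:
            for j in STATES:
                if i != j and (i, j) not in PERMITTED_TRANSITIONS:
                    if np.any(self.probs[:, i - 1, j - 1] != 0):
                        raise ValueError(f"forbidden transition {i}->{j} has mass")

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: stratum, arm, day, from, to, prob, se, provenance."""
        rows = []
        for t in range(1, self.horizon + 1):
            for i in STATES:
                for j in STATES:
                    p = self.probs[t - 1, i - 1, j - 1]
                    if p == 0 and i != j:
                        continue
                    rows.append(
                        dict(
                            stratum=self.stratum,
                            arm=self.arm,
                            day=t,
                            **{"from": i, "to": j},
                            prob=p,
                            se=self.se[t - 1, i - 1, j - 1],
                            provenance=self.provenance,
                        )
                    )
        return pd.DataFrame(rows)


@dataclass
class OccupationCurve:
    """State-occupation probabilities pi_j(t) from a given start state.

    ``probs[t]`` is the occupation vector after t days (row t=0 is the
    start-state indicator).  ``se`` is optional, matching ``probs``.
    """

    start_state: int
    probs: np.ndarray  # (horizon+1, 4)
    se: Optional[np.ndarray] = None
    degenerate: bool = False

    def validate(self) -> None:
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("occupation vectors must sum to 1")
        for s in ABSORBING_STATES:
            col = self.probs[:, s - 1]
            if np.any(np.diff(col) < -1e-12):
                raise ValueError(f"occupation of absorbing state {s} must be monotone")


def counting_process(events: pd.DataFrame, horizon: int) -> CountingProcess:
    """Tabulate at-risk and transition counts on the daily grid 1..horizon.

    A record with ``entry_day`` a and ``exit_day`` b in state i contributes
    to Y_i(t) for a < t <= b; an event record additionally contributes one
    count to d_{i,dest}(b).  Censored records contribute to no d.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    Y = np.zeros((_NSTATES, horizon), dtype=float)
    d = {tr: np.zeros(horizon, dtype=float) for tr in PERMITTED_TRANSITIONS}
    entry = events["entry_day"].to_numpy(dtype=int)
    exit_ = events["exit_day"].to_numpy(dtype=int)
    origin = events["origin_state"].to_numpy(dtype=int)
    status = events["status"].to_numpy()
    dest = events["dest_state"].to_numpy(dtype=object)
    for a, b, o, st, de in zip(entry, exit_, origin, status, dest):
        lo, hi = max(a + 1, 1), min(b, horizon)
        if lo <= hi:
            Y[o - 1, lo - 1 : hi] += 1.0
        if st == "event" and b <= horizon and not pd.isna(de):
            tr = (o, int(de))
            if tr not in d:
                raise ValueError(f"illegal transition {tr} in event history")
            d[tr][b - 1] += 1.0
    cp = CountingProcess(horizon=horizon, at_risk=Y, transitions=d)
    cp.validate()
    return cp


def daily_transition_probabilities(
    cp: CountingProcess,
    provenance: str = "nonparametric",
    stratum: Optional[str] = None,
    arm: Optional[str] = None,
) -> DailyTransitionModel:
    """Crude daily transition matrices p_ij(t) = d_ij(t) / Y_i(t).

    Stay probabilities take the residual mass; absorbing states get
    identity rows.  Days with an empty risk set in a transient state emit
    the identity row (flagged, standard error absent) — the only
    convention that preserves row normalization.  Per-cell standard errors
    are binomial, sqrt(p(1-p)/Y).
    """
    T = cp.horizon
    probs = np.zeros((T, _NSTATES, _NSTATES))
    se = np.full((T, _NSTATES, _NSTATES), np.nan)
    empty = np.zeros((T, _NSTATES), dtype=bool)
    probs[:, :, :] = np.eye(_NSTATES)[None, :, :]
    for t in range(1, T + 1):
        for i in (1, 2):
            Yi = cp.at_risk[i - 1, t - 1]
            if Yi == 0:
                empty[t - 1, i - 1] = True
                continue
            off = 0.0
            for (o, j), dd in cp.transitions.items():
                if o != i:
                    continue
                p = dd[t - 1] / Yi
                probs[t - 1, i - 1, j - 1] = p
                se[t - 1, i - 1, j - 1] = np.sqrt(p * (1.0 - p) / Yi)
                off += p
            probs[t - 1, i - 1, i - 1] = 1.0 - off
            se[t - 1, i - 1, i - 1] = np.sqrt(off * (1.0 - off) / Yi)
    model = DailyTransitionModel(
        horizon=T,
        probs=probs,
        se=se,
        provenance=provenance,
        stratum=stratum,
        arm=arm,
        empty_risk_set=empty,
    )
    model.validate()
    return model


def aalen_johansen(cp: CountingProcess, start_state: int) -> OccupationCurve:
    """Aalen-Johansen state-occupation probabilities from ``start_state``.

    Computes P(0, t) as the product over days s <= t of (I + dA(s)), with
    off-diagonal increment dA_ij(s) = d_ij(s) / Y_i(s) (zero on empty risk
    sets) and diagonal minus the row sum; the returned curve is the
    start-state row.  For an absorbing start state the curve is degenerate
    (probability one forever) and flagged as such.
    """
    if start_state not in STATES:
        raise ValueError(f"unknown state {start_state}")
    T = cp.horizon
    out = np.zeros((T + 1, _NSTATES))
    out[0, start_state - 1] = 1.0
    if start_state in ABSORBING_STATES:
        out[:, start_state - 1] = 1.0
        return OccupationCurve(start_state=start_state, probs=out, degenerate=True)
    model = daily_transition_probabilities(cp)
    P = np.eye(_NSTATES)
    for t in range(1, T + 1):
        P = P @ model.probs[t - 1]
        out[t] = P[start_state - 1]
    curve = OccupationCurve(start_state=start_state, probs=out)
    curve.validate()
    return curve


def _resample_subjects(events: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    ids = events["subject_id"].unique()
    pick = rng.choice(ids, size=len(ids), replace=True)
    parts = []
    grouped = dict(tuple(events.groupby("subject_id", sort=False)))
    for k, sid in enumerate(pick):
        g = grouped[sid].copy()
        g["subject_id"] = f"bs{k}"
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def occupation_bootstrap_se(
    events: pd.DataFrame,
    horizon: int,
    start_state: int,
    n_boot: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Pointwise bootstrap standard errors for the occupation curve.

    Resamples subjects with replacement ``n_boot`` times and returns the
    elementwise standard deviation of the replicate curves, shaped like
    ``OccupationCurve.probs``.
    """
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, horizon + 1, _NSTATES))
    for b in range(n_boot):
        bs = _resample_subjects(events, rng)
        reps[b] = aalen_johansen(counting_process(bs, horizon), start_state).probs
    return reps.std(axis=0, ddof=1)


def transition_bootstrap_se(
    events: pd.DataFrame, horizon: int, n_boot: int = 500, seed: int = 0
) -> np.ndarray:
    """Subject-level bootstrap standard errors for the daily matrices."""
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, horizon, _NSTATES, _NSTATES))
    for b in range(n_boot):
        bs = _resample_subjects(events, rng)
        reps[b] = daily_transition_probabilities(counting_process(bs, horizon)).probs
    return reps.std(axis=0, ddof=1)


def estimate_models_by_group(
    events: pd.DataFrame, horizon: int
) -> Dict[Tuple[str, str], DailyTransitionModel]:
    """Nonparametric daily models for every (stratum, arm) in the table."""
    out: Dict[Tuple[str, str], DailyTransitionModel] = {}
    for (stratum, arm), grp in events.groupby(["stratum", "arm"], sort=False):
        cp = counting_process(grp, horizon)
        out[(stratum, arm)] = daily_transition_probabilities(
            cp, stratum=stratum, arm=arm
        )
        if out[(stratum, arm)].empty_risk_set[:, :2].any():
            warnings.warn(
                f"{stratum}/{arm}: empty risk set on some days; identity rows emitted"
            )
    return out
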