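"""Daily-cycle Markov cost-utility engine.

Three empiric-antibiotic strategies (adherent, over-treated, under-treated)
are compared within an admission stratum over a 14-day horizon (one cycle =
24 h; sensitivity analyses extend to 30).  Each strategy has its own daily
transition matrices; costs and utilities accrue to the state occupied
*during* each cycle, i.e. after applying that cycle's matrix, so a patient
discharged on day 1 accrues a full horizon of discharge utility.  No
half-cycle correction and no discounting are applied (daily cycles over at
most 30 days).

Accrual rules: admitted ICU patients incur the day-indexed ICU bed cost
(index = days spent admitted so far, capped at 8) plus the intravenous
antibiotic cost; admitted ward patients the ward bed cost plus IV drugs;
clinically stable patients the ward bed cost plus oral drugs (ICU patients
transfer to the ward on reaching stability); discharge and death accrue
nothing.  Utilities: admission state (stratum-specific), stable 0.82,
discharge 1, death 0 by default.

The engine offers a deterministic cohort trace, a patient-level Monte
Carlo microsimulation, probabilistic sensitivity analysis (every beta and
gamma parameter drawn once per iteration), incremental/dominance analysis
against the adherent base case, cost-effectiveness acceptability curves
over a willingness-to-pay grid, and deterministic sensitivity grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import ParameterSet, TransitionPrior

__all__ = [
    "MarkovSpec",
    "CohortTrace",
    "MicrosimResult",
    "PSADraws",
    "run_cohort",
    "run_microsimulation",
    "run_psa",
    "incremental_analysis",
    "summarize_psa",
    "ceac",
    "default_wtp_grid",
    "dsa_grid",
]

_START = np.array([1.0, 0.0, 0.0, 0.0])


@dataclass
class MarkovSpec:
    """One stratum's model: horizon, per-strategy transitions, parameters."""

    stratum: str
    params: ParameterSet
    horizon: int = 14

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.stratum != self.params.stratum:
            raise ValueError("spec stratum and parameter-set stratum disagree")
        for arm, prior in self.params.transitions.items():
            if prior.mean.shape[0] < self.horizon:
                raise ValueError(
                    f"strategy {arm!r}: transition model covers "
                    f"{prior.mean.shape[0]} days < horizon {self.horizon}"
                )

    @property
    def strategies(self) -> List[str]:
        return sorted(self.params.transitions)


def _state_inputs(
    spec: MarkovSpec, strategy: str, overrides: Optional[Mapping] = None
) -> Tuple[np.ndarray, float, float, float]:
    """Per-cycle state-1 cost vector, state-2 cost, and utilities (means)."""
    ov = overrides or {}
    cost = spec.params.cost
    iv = ov.get("iv_cost", {}).get(
        strategy, cost.drug_iv_daily[(spec.stratum, strategy)]
    )
    oral = ov.get("oral_cost", {}).get(
        strategy, cost.drug_oral_daily[(spec.stratum, strategy)]
    )
    ward_bed = ov.get("ward_daily_cost", cost.ward_daily.mean)
    if spec.stratum == "icu":
        icu_flat = ov.get("icu_daily_cost")
        bed = np.array(
            [
                icu_flat if icu_flat is not None else cost.icu_day(t).mean
                for t in range(1, spec.horizon + 1)
            ]
        )
    else:
        bed = np.full(spec.horizon, ward_bed)
    c1 = bed + iv
    c2 = ward_bed + oral
    u1 = ov.get(
        "utility_admission", spec.params.utility.admission(spec.stratum).mean
    )
    u2 = ov.get("utility_stable", spec.params.utility.stable.mean)
    return c1, float(c2), float(u1), float(u2)


@dataclass
class CohortTrace:
    """Deterministic cohort expectation for one strategy."""

    strategy: str
    occupation: np.ndarray  # (horizon+1, 4); row 0 is the start vector
    cycle_cost: np.ndarray  # (horizon,)
    cycle_utility: np.ndarray  # (horizon,)

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def total_utility(self) -> float:
        return float(self.cycle_utility.sum())


def _validate_matrices(mats: np.ndarray) -> None:
    if np.any(mats < -1e-12) or np.any(mats > 1 + 1e-12):
        raise ValueError("transition probabilities outside [0, 1]")
    if not np.allclose(mats.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError("transition-matrix rows must sum to 1")


def run_cohort(
    spec: MarkovSpec,
    strategy: str,
    overrides: Optional[Mapping] = None,
    start: np.ndarray = _START,
) -> CohortTrace:
    """Propagate the cohort through the daily matrices and accrue values.

    Uses the point-estimate transition matrices and mean costs/utilities
    (optionally overridden for deterministic sensitivity analysis).
    """
    prior = spec.params.transitions[strategy]
    T = spec.horizon
    mats = prior.mean[:T]
    _validate_matrices(mats)
    c1, c2, u1, u2 = _state_inputs(spec, strategy, overrides)
    udis = spec.params.utility.discharge
    udead = spec.params.utility.dead
    occ = np.zeros((T + 1, 4))
    occ[0] = start
    cost = np.zeros(T)
    util = np.zeros(T)
    for t in range(1, T + 1):
        occ[t] = occ[t - 1] @ mats[t - 1]
        cost[t - 1] = occ[t, 0] * c1[t - 1] + occ[t, 1] * c2
        util[t - 1] = (
            occ[t, 0] * u1 + occ[t, 1] * u2 + occ[t, 2] * udis + occ[t, 3] * udead
        )
    return CohortTrace(strategy=strategy, occupation=occ, cycle_cost=cost,
                       cycle_utility=util)


@dataclass
class MicrosimResult:
    """Patient-level Monte Carlo results for one strategy."""

    strategy: str
    cost: np.ndarray  # (n_patients,)
    utility: np.ndarray
    los: np.ndarray  # first cycle in an absorbing state (horizon if never)
    icu_los: Optional[np.ndarray]  # first cycle out of state 1 (ICU stratum)

    @property
    def median_los(self) -> float:
        return float(np.median(self.los))


def run_microsimulation(
    spec: MarkovSpec,
    strategy: str,
    n_patients: int = 10_000,
    seed: int = 0,
) -> MicrosimResult:
    """Sample individual hospital courses through the daily matrices.

    Costs and utilities accrue per patient with the same rules and mean
    parameters as :func:`run_cohort`; the empirical means therefore agree
    with the cohort expectations up to Monte Carlo error.  Length of stay
    is the first cycle entering discharge or death (the horizon when the
    patient is still in hospital at the end); in the ICU stratum the ICU
    length of stay is the first cycle out of the admission state.
    """
    rng = np.random.default_rng(seed)
    prior = spec.params.transitions[strategy]
    T = spec.horizon
    mats = prior.mean[:T]
    _validate_matrices(mats)
    cum = np.cumsum(mats, axis=2)  # (T, 4, 4)
    c1, c2, u1, u2 = _state_inputs(spec, strategy)
    state = np.zeros(n_patients, dtype=np.int64)  # 0-based state index
    cost = np.zeros(n_patients)
    util = np.zeros(n_patients)
    los = np.full(n_patients, T, dtype=np.int64)
    icu_los = np.full(n_patients, T, dtype=np.int64)
    unabsorbed = np.ones(n_patients, dtype=bool)
    in_state1 = np.ones(n_patients, dtype=bool)
    for t in range(1, T + 1):
        active = state < 2
        if active.any():
            u = rng.random(active.sum())
            rows = cum[t - 1, state[active]]
            state[active] = (u[:, None] >= rows).sum(axis=1)
        los[unabsorbed & (state >= 2)] = t
        unabsorbed &= state < 2
        icu_los[in_state1 & (state != 0)] = t
        in_state1 &= state == 0
        cost += np.where(state == 0, c1[t - 1], 0.0) + np.where(state == 1, c2, 0.0)
        util += (
            np.where(state == 0, u1, 0.0)
            + np.where(state == 1, u2, 0.0)
            + np.where(state == 2, spec.params.utility.discharge, 0.0)
            + np.where(state == 3, spec.params.utility.dead, 0.0)
        )
    return MicrosimResult(
        strategy=strategy,
        cost=cost,
        utility=util,
        los=los,
        icu_los=icu_los if spec.stratum == "icu" else None,
    )


@dataclass
class PSADraws:
    """Sampled (cost, utility) pairs per strategy per PSA iteration."""

    draws: pd.DataFrame  # columns: iteration, strategy, cost, utility
    strategies: List[str] = field(default_factory=list)

    def pivot(self, value: str) -> pd.DataFrame:
        return self.draws.pivot(index="iteration", columns="strategy", values=value)


def _sample_matrices(
    prior: TransitionPrior, horizon: int, K: int, rng: np.random.Generator
) -> np.ndarray:
    """K sampled daily matrices with projective row renormalization.

    Each non-degenerate off-diagonal cell is drawn from its beta; the stay
    probability takes the residual.  If sampled off-diagonal mass exceeds
    1 the row is rescaled to sum to 1 with stay probability 0, preserving
    the relative competing risks.
    """
    mean = prior.mean[:horizon]
    mats = np.broadcast_to(mean, (K,) + mean.shape).copy()
    free = ~prior.fixed[:horizon]
    if free.any():
        idx = np.where(free)
        a = prior.alpha[:horizon][idx]
        b = prior.beta[:horizon][idx]
        samples = rng.beta(a, b, size=(K, len(a)))
        mats[:, idx[0], idx[1], idx[2]] = samples
    for i in (0, 1):  # transient rows
        row = mats[:, :, i, :]
        row[:, :, i] = 0.0
        s = row.sum(axis=2)
        over = s > 1.0
        if over.any():
            row[over] /= s[over][:, None]
            s = row.sum(axis=2)
        row[:, :, i] = 1.0 - s
        mats[:, :, i, :] = row
    return mats


def run_psa(
    spec: MarkovSpec, K: int = 10_000, seed: int = 0
) -> PSADraws:
    """Probabilistic sensitivity analysis.

    Per iteration, every beta utility, gamma daily bed cost (one draw per
    ICU day index and one for the ward) and beta transition cell is drawn
    once and applied to all cycles — parameter uncertainty, not daily
    stochastic variation — and the cohort model is evaluated per strategy.
    """
    rng = np.random.default_rng(seed)
    T = spec.horizon
    cost = spec.params.cost
    util = spec.params.utility
    # parameter draws shared across strategies within an iteration
    ward_bed = cost.ward_daily.sample(rng, size=K)
    if spec.stratum == "icu":
        icu_draws = np.column_stack(
            [cost.icu_daily[d].sample(rng, size=K) for d in range(8)]
        )
        bed1 = icu_draws[:, np.minimum(np.arange(1, T + 1), 8) - 1]  # (K, T)
        u1 = util.icu_admission.sample(rng, size=K)
    else:
        bed1 = np.repeat(ward_bed[:, None], T, axis=1)
        u1 = util.ward_admission.sample(rng, size=K)
    u2 = util.stable.sample(rng, size=K)
    rows = []
    for strategy in spec.strategies:
        mats = _sample_matrices(spec.params.transitions[strategy], T, K, rng)
        iv = cost.drug_iv_daily[(spec.stratum, strategy)]
        oral = cost.drug_oral_daily[(spec.stratum, strategy)]
        c1 = bed1 + iv  # (K, T)
        c2 = ward_bed + oral  # (K,)
        pi = np.tile(_START, (K, 1))
        tot_cost = np.zeros(K)
        tot_util = np.zeros(K)
        for t in range(1, T + 1):
            pi = np.einsum("ki,kij->kj", pi, mats[:, t - 1])
            tot_cost += pi[:, 0] * c1[:, t - 1] + pi[:, 1] * c2
            tot_util += (
                pi[:, 0] * u1
                + pi[:, 1] * u2
                + pi[:, 2] * util.discharge
                + pi[:, 3] * util.dead
            )
        rows.append(
            pd.DataFrame(
                dict(
                    iteration=np.arange(K),
                    strategy=strategy,
                    cost=tot_cost,
                    utility=tot_util,
                )
            )
        )
    return PSADraws(
        draws=pd.concat(rows, ignore_index=True), strategies=spec.strategies
    )


def _dominance_labels(results: Mapping[str, Tuple[float, float]]) -> Dict[str, str]:
    # strict on cost, weak on utility: a strictly cheaper strategy with
    # utility at least as high dominates (so pure cost differences at tied
    # utility still resolve); identical strategies are trade-offs
    labels = {}
    for s, (c, u) in results.items():
        others = [(c2, u2) for s2, (c2, u2) in results.items() if s2 != s]
        if all(c < c2 and u >= u2 for c2, u2 in others):
            labels[s] = "dominant"
        elif any(c2 < c and u2 >= u for c2, u2 in others):
            labels[s] = "dominated"
        else:
            labels[s] = "trade-off"
    return labels


def incremental_analysis(
    results: Mapping[str, Tuple[float, float]], base: str = "adherent"
) -> pd.DataFrame:
    """Incremental cost/utility versus the base strategy, with dominance.

    ``results`` maps strategy -> (expected cost, expected utility).  A
    strategy is *dominant* when it is cheaper and more effective than
    every comparator, *dominated* when some comparator is cheaper and
    more effective than it, otherwise a *trade-off*; incremental
    cost-utility ratios are reported only for trade-off strategies.
    """
    if base not in results:
        raise ValueError(f"base strategy {base!r} not among results")
    labels = _dominance_labels(results)
    bc, bu = results[base]
    rows = []
    for s, (c, u) in results.items():
        dc, du = c - bc, u - bu
        icer = np.nan
        if s != base and labels[s] == "trade-off" and du != 0.0:
            icer = dc / du
        rows.append(
            dict(
                strategy=s,
                cost=c,
                utility=u,
                incremental_cost=dc,
                incremental_utility=du,
                icer=icer,
                dominance=labels[s],
            )
        )
    return pd.DataFrame(rows).set_index("strategy")


def summarize_psa(draws: PSADraws, base: str = "adherent") -> pd.DataFrame:
    """Per-strategy means and 2.5th-97.5th percentile intervals.

    Incremental quantities are computed per iteration against the base
    strategy and summarized the same way; dominance labels apply to the
    PSA means.
    """
    c = draws.pivot("cost")
    u = draws.pivot("utility")
    means = {s: (c[s].mean(), u[s].mean()) for s in draws.strategies}
    inc = incremental_analysis(means, base=base)
    rows = []
    for s in draws.strategies:
        dc = c[s] - c[base]
        du = u[s] - u[base]
        rows.append(
            dict(
                strategy=s,
                cost=c[s].mean(),
                cost_lo=c[s].quantile(0.025),
                cost_hi=c[s].quantile(0.975),
                utility=u[s].mean(),
                utility_lo=u[s].quantile(0.025),
                utility_hi=u[s].quantile(0.975),
                incremental_cost=dc.mean(),
                incremental_cost_lo=dc.quantile(0.025),
                incremental_cost_hi=dc.quantile(0.975),
                incremental_utility=du.mean(),
                incremental_utility_lo=du.quantile(0.025),
                incremental_utility_hi=du.quantile(0.975),
                dominance=inc.loc[s, "dominance"],
            )
        )
    return pd.DataFrame(rows).set_index("strategy")


def default_wtp_grid(max_wtp: float = 1000.0, intervals: int = 20) -> np.ndarray:
    """Willingness-to-pay grid in USD per quality-adjusted life day."""
    return np.linspace(0.0, max_wtp, intervals + 1)


def ceac(
    draws: PSADraws, wtp_grid: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    Per threshold, the accepted strategy in each iteration maximizes net
    monetary benefit (wtp * utility - cost); exact ties resolve to the
    lowest cost, then alphabetically.  Returns a frame indexed by ``wtp``
    with one acceptance-fraction column per strategy (rows sum to 1).
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    strategies = draws.strategies  # already sorted alphabetically
    c = draws.pivot("cost")[strategies].to_numpy()
    u = draws.pivot("utility")[strategies].to_numpy()
    K = c.shape[0]
    out = np.zeros((len(wtp_grid), len(strategies)))
    for gi, lam in enumerate(wtp_grid):
        nmb = lam * u - c
        best = nmb.max(axis=1, keepdims=True)
        tied = nmb == best
        # break ties by lowest cost, then alphabetical (column order)
        cost_masked = np.where(tied, c, np.inf)
        winner = cost_masked.argmin(axis=1)
        out[gi] = np.bincount(winner, minlength=len(strategies)) / K
    return pd.DataFrame(out, index=pd.Index(wtp_grid, name="wtp"), columns=strategies)


# parameter axes recognized by the deterministic sensitivity grid
_DSA_PARAMS = (
    "iv_cost:adherent",
    "iv_cost:over",
    "iv_cost:under",
    "oral_cost:adherent",
    "oral_cost:over",
    "oral_cost:under",
    "ward_daily_cost",
    "icu_daily_cost",
    "utility_admission",
    "utility_stable",
)


def _apply_axis(overrides: dict, name: str, value: float) -> None:
    if name not in _DSA_PARAMS:
        raise ValueError(f"unknown sensitivity parameter {name!r}; "
                         f"known: {sorted(_DSA_PARAMS)}")
    if ":" in name:
        kind, arm = name.split(":")
        overrides.setdefault(f"{kind}", {})[arm] = value
    else:
        overrides[name] = value


def dsa_grid(
    spec: MarkovSpec,
    axes: Iterable[Tuple[str, Tuple[float, float], int]],
) -> pd.DataFrame:
    """Deterministic sensitivity analysis over a cartesian parameter grid.

    ``axes`` is a list of ``(parameter, (low, high), n_intervals)``; each
    axis contributes ``n_intervals + 1`` equally spaced points including
    both endpoints.  At each gridpoint the named parameters are fixed,
    everything else stays at its mean, the cohort model is evaluated per
    strategy, and the strictly dominant strategy (or ``"none"``) is
    recorded.
    """
    axes = list(axes)
    grids = [np.linspace(lo, hi, n + 1) for _, (lo, hi), n in axes]
    names = [name for name, _, _ in axes]
    for name in names:
        _apply_axis({}, name, 0.0)  # validate names up front
    rows = []
    for point in _iterproduct(*grids):
        overrides: dict = {}
        for name, value in zip(names, point):
            _apply_axis(overrides, name, value)
        results = {}
        for s in spec.strategies:
            trace = run_cohort(spec, s, overrides=overrides)
            results[s] = (trace.total_cost, trace.total_utility)
        labels = _dominance_labels(results)
        dominant = next((s for s, l in labels.items() if l == "dominant"), "none")
        rows.append(dict(zip(names, point), dominant=dominant))
    return pd.DataFrame(rows)
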