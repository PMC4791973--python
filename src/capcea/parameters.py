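"""Probabilistic cost and utility inputs for the Markov model.

Daily hospital costs are modelled as gamma distributions and utilities and
transition probabilities as beta distributions, each parameterized by the
method of moments from a stated mean and standard deviation so the fitted
distribution reproduces the targets exactly.  Defaults are the published
inputs: a dynamic ICU daily-cost schedule declining from $5132 (SD $4767)
on ICU day 1 to $3825 (SD $2658) on day 8 and thereafter, a static ward
cost of $1060 (SD $1141) per day, per-arm daily intravenous and oral
antibiotic costs, and expert-panel utilities — ICU admission 0.30 (0.063),
ward admission 0.53 (0.10), clinically stable 0.82 (0.13), discharge fixed
at 1, death fixed at 0.  All monetary values are 2013 US dollars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .multistate import DailyTransitionModel

__all__ = [
    "GammaParams",
    "BetaParams",
    "CostModel",
    "UtilityModel",
    "TransitionPrior",
    "ParameterSet",
    "beta_from_moments",
    "gamma_from_moments",
    "mean_daily_drug_cost",
    "icu_cost_schedule",
    "default_cost_model",
    "default_utility_model",
    "build_parameter_set",
]

ICU_DAY1_COST = (5132.0, 4767.0)  # (mean, sd), ICU day 1
ICU_DAY8_COST = (3825.0, 2658.0)  # day 8 and thereafter
WARD_DAILY_COST = (1060.0, 1141.0)

#: fixed mean daily antibiotic costs (USD) by stratum and arm
DRUG_IV_DAILY = {
    ("icu", "adherent"): 41.82,
    ("icu", "over"): 64.85,
    ("icu", "under"): 36.57,
    ("ward", "adherent"): 30.61,
    ("ward", "over"): 43.91,
    ("ward", "under"): 34.97,
}
DRUG_ORAL_DAILY = {
    ("icu", "adherent"): 12.58,
    ("icu", "over"): 20.50,
    ("icu", "under"): 9.28,
    ("ward", "adherent"): 14.75,
    ("ward", "over"): 23.10,
    ("ward", "under"): 9.53,
}

UTILITY_MOMENTS = {
    "icu_admission": (0.30, 0.063),
    "ward_admission": (0.53, 0.10),
    "stable": (0.82, 0.13),
}


@dataclass(frozen=True)
class GammaParams:
    """Gamma(kappa, theta): shape kappa, scale theta (USD)."""

    kappa: float
    theta: float

    @property
    def mean(self) -> float:
        return self.kappa * self.theta

    @property
    def sd(self) -> float:
        return np.sqrt(self.kappa) * self.theta

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.kappa, self.theta, size=size)


@dataclass(frozen=True)
class BetaParams:
    """Beta(alpha, beta) on [0, 1]."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


def beta_from_moments(mean: float, sd: float) -> BetaParams:
    """Beta shapes matching a mean and standard deviation exactly.

    With nu = mean(1-mean)/sd^2 - 1, alpha = mean*nu and beta =
    (1-mean)*nu.  Requires 0 < mean < 1 and sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ValueError(f"sd must be positive, got {sd}")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"no beta distribution has mean {mean} and sd {sd}: "
            f"variance must be below mean(1-mean) = {mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return BetaParams(alpha=mean * nu, beta=(1.0 - mean) * nu)


def gamma_from_moments(mean: float, sd: float) -> GammaParams:
    """Gamma shape/scale matching a mean and standard deviation exactly."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError("mean and sd must be positive")
    return GammaParams(kappa=mean * mean / (sd * sd), theta=sd * sd / mean)


def icu_cost_schedule(
    day1: Tuple[float, float] = ICU_DAY1_COST,
    day8: Tuple[float, float] = ICU_DAY8_COST,
    schedule: Optional[Mapping[int, Tuple[float, float]]] = None,
) -> Tuple[GammaParams, ...]:
    """Gamma distributions for ICU days 1..8 (day 8 reused thereafter).

    Means and SDs for days 2-7 interpolate linearly between the day-1 and
    day-8 anchors; ``schedule`` may override any day with an explicit
    (mean, sd) pair.
    """
    out = []
    for day in range(1, 9):
        w = (day - 1) / 7.0
        mean = (1 - w) * day1[0] + w * day8[0]
        sd = (1 - w) * day1[1] + w * day8[1]
        if schedule and day in schedule:
            mean, sd = schedule[day]
        out.append(gamma_from_moments(mean, sd))
    means = [g.mean for g in out]
    if any(np.diff(means) > 1e-9):
        raise ValueError("ICU daily cost means must be non-increasing in day")
    return tuple(out)


@dataclass
class CostModel:
    """Daily cost inputs: hospital bed costs and per-arm antibiotic costs."""

    icu_daily: Tuple[GammaParams, ...]  # days 1..8; day >= 8 reuses index 7
    ward_daily: GammaParams
    drug_iv_daily: Dict[Tuple[str, str], float]
    drug_oral_daily: Dict[Tuple[str, str], float]

    def icu_day(self, day: int) -> GammaParams:
        return self.icu_daily[min(day, 8) - 1]


@dataclass
class UtilityModel:
    """Per-state utility distributions; discharge and death are degenerate."""

    icu_admission: BetaParams
    ward_admission: BetaParams
    stable: BetaParams
    discharge: float = 1.0
    dead: float = 0.0

    def admission(self, stratum: str) -> BetaParams:
        return self.icu_admission if stratum == "icu" else self.ward_admission


def default_cost_model(**overrides) -> CostModel:
    return CostModel(
        icu_daily=icu_cost_schedule(),
        ward_daily=gamma_from_moments(*WARD_DAILY_COST),
        drug_iv_daily=dict(DRUG_IV_DAILY),
        drug_oral_daily=dict(DRUG_ORAL_DAILY),
        **overrides,
    )


def default_utility_model() -> UtilityModel:
    return UtilityModel(
        icu_admission=beta_from_moments(*UTILITY_MOMENTS["icu_admission"]),
        ward_admission=beta_from_moments(*UTILITY_MOMENTS["ward_admission"]),
        stable=beta_from_moments(*UTILITY_MOMENTS["stable"]),
    )


def mean_daily_drug_cost(
    regimens: pd.DataFrame, prices: pd.DataFrame
) -> pd.DataFrame:
    """Average daily antibiotic cost per stratum x arm from a price table.

    ``regimens`` has one row per patient with columns ``subject_id,
    regimen, arm, stratum``; ``prices`` maps ``regimen`` to
    ``iv_daily_usd`` and ``oral_daily_usd``.  Returns a frame indexed by
    (stratum, arm) with columns ``iv_mean`` and ``oral_mean`` — the
    arithmetic mean over patients in the cell.
    """
    missing = sorted(set(regimens["regimen"]) - set(prices["regimen"]))
    if missing:
        raise ValueError(f"no price entry for regimens: {missing}")
    merged = regimens.merge(prices, on="regimen", how="left")
    out = (
        merged.groupby(["stratum", "arm"])[["iv_daily_usd", "oral_daily_usd"]]
        .mean()
        .rename(columns={"iv_daily_usd": "iv_mean", "oral_daily_usd": "oral_mean"})
    )
    if out.empty:
        warnings.warn("empty regimen table; no drug costs computed")
    return out


@dataclass
class TransitionPrior:
    """Beta uncertainty attached to every sampled daily transition cell.

    ``mean`` holds the point-estimate matrices; ``alpha``/``beta`` hold
    beta shapes for each off-diagonal permitted cell with a usable
    standard error, NaN elsewhere; ``fixed`` marks cells kept at their
    point estimate (degenerate probabilities, missing SEs, structural
    zeros, stay cells and absorbing rows).
    """

    mean: np.ndarray  # (T, 4, 4)
    alpha: np.ndarray
    beta: np.ndarray
    fixed: np.ndarray  # bool


def transition_prior(model: DailyTransitionModel) -> TransitionPrior:
    """Beta distributions for the sampled cells of a daily model.

    Each off-diagonal permitted cell with probability strictly inside
    (0, 1) and a finite positive SE becomes Beta(mean=p, sd=se); an SE too
    large for a valid beta is truncated just inside the feasibility bound
    (with a warning).  All other cells stay fixed.
    """
    T = model.horizon
    mean = model.probs.copy()
    alpha = np.full_like(mean, np.nan)
    beta = np.full_like(mean, np.nan)
    fixed = np.ones_like(mean, dtype=bool)
    n_trunc = 0
    for t in range(T):
        for i in (1, 2):
            for j in range(4):
                if i - 1 == j:
                    continue
                p = mean[t, i - 1, j]
                se = model.se[t, i - 1, j]
                if not (0.0 < p < 1.0) or not np.isfinite(se) or se <= 0.0:
                    continue
                cap = 0.99 * np.sqrt(p * (1.0 - p))
                if se >= cap:
                    se = cap
                    n_trunc += 1
                bp = beta_from_moments(p, se)
                alpha[t, i - 1, j] = bp.alpha
                beta[t, i - 1, j] = bp.beta
                fixed[t, i - 1, j] = False
    if n_trunc:
        warnings.warn(
            f"{n_trunc} transition cell SD(s) exceeded the beta feasibility "
            "bound and were truncated"
        )
    return TransitionPrior(mean=mean, alpha=alpha, beta=beta, fixed=fixed)


@dataclass
class ParameterSet:
    """Everything the cost-utility engine samples or evaluates.

    ``transitions`` maps each strategy arm to the beta-uncertain daily
    transition model for the stratum being analysed.
    """

    stratum: str
    cost: CostModel
    utility: UtilityModel
    transitions: Dict[str, TransitionPrior] = field(default_factory=dict)


def build_parameter_set(
    stratum: str,
    transition_models: Mapping[str, DailyTransitionModel],
    cost: Optional[CostModel] = None,
    utility: Optional[UtilityModel] = None,
) -> ParameterSet:
    """Assemble the probabilistic inputs for one stratum.

    ``transition_models`` maps strategy arm -> fitted
    :class:`DailyTransitionModel` (with standard errors); transition cells
    become beta distributions via the method of moments, degenerate cells
    stay fixed.  ``cost`` and ``utility`` default to the published inputs.
    """
    return ParameterSet(
        stratum=stratum,
        cost=cost if cost is not None else default_cost_model(),
        utility=utility if utility is not None else default_utility_model(),
        transitions={
            arm: transition_prior(m) for arm, m in transition_models.items()
        },
    )
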