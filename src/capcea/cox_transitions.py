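"""Cause-specific Cox regression per permitted transition.

One proportional-hazards model is fit per permitted transition, treating
competing exits from the same origin state as censoring.  The time scale
is days since admission (clock forward); sojourns entering a state later
than day 0 enter the risk set by left truncation.  Ties — ubiquitous on a
daily grid — are handled with the Breslow approximation, which keeps the
Breslow baseline-hazard increments consistent with the crude estimator
d_ij(t)/Y_i(t): at beta = 0 the two coincide exactly, and the predicted
daily matrices reduce to the nonparametric ones.

Estimation is Newton-Raphson on the log partial likelihood with step
halving, converging on the score norm (1e-8, at most 50 iterations).
Monotone likelihoods (separation) are detected by coefficients escaping
[-10, 10] and are capped there with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .multistate import DailyTransitionModel, _NSTATES
from .states import ABSORBING_STATES, PERMITTED_TRANSITIONS, STATES
from .synthetic_cohort import covariate_columns

__all__ = [
    "CoxFit",
    "TransitionFit",
    "fit_cause_specific_cox",
    "predict_daily_probabilities",
    "modal_profile",
    "parametric_bootstrap_se",
]

MAX_ABS_COEF = 10.0


@dataclass
class TransitionFit:
    transition: Tuple[int, int]
    covariates: List[str]
    coef: np.ndarray
    se: np.ndarray
    baseline_increments: np.ndarray  # dA0_ij(t), index t-1, Breslow
    loglik: float
    loglik_null: float
    n_events: int
    converged: bool
    capped: bool = False


@dataclass
class CoxFit:
    """Container of per-transition Cox fits sharing a covariate list."""

    covariates: List[str]
    horizon: int
    fits: Dict[Tuple[int, int], TransitionFit] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.fits.values())

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "horizon": self.horizon,
            "transitions": {
                f"{i}->{j}": {
                    "coef": dict(zip(f.covariates, f.coef.tolist())),
                    "se": dict(zip(f.covariates, f.se.tolist())),
                    "baseline_increments": f.baseline_increments.tolist(),
                    "loglik": f.loglik,
                    "loglik_null": f.loglik_null,
                    "n_events": f.n_events,
                    "converged": f.converged,
                }
                for (i, j), f in self.fits.items()
            },
        }


def _transition_arrays(
    events: pd.DataFrame, transition: Tuple[int, int], covariates: List[str]
):
    i, j = transition
    sub = events[events["origin_state"] == i]
    entry = sub["entry_day"].to_numpy(dtype=float)
    exit_ = sub["exit_day"].to_numpy(dtype=float)
    event = (
        (sub["status"] == "event") & (sub["dest_state"].astype("float") == j)
    ).to_numpy()
    Z = sub[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(sub), 0))
    return entry, exit_, event, Z


def breslow_loglik(beta, entry, exit_, event, Z):
    """Log partial likelihood with Breslow ties and left truncation."""
    eta = Z @ beta
    ll = 0.0
    for t in np.unique(exit_[event]):
        at_risk = (entry < t) & (exit_ >= t)
        cases = event & (exit_ == t)
        d = cases.sum()
        ll += eta[cases].sum() - d * np.log(np.exp(eta[at_risk]).sum())
    return ll


def _score_info(beta, entry, exit_, event, Z):
    p = Z.shape[1]
    eta = Z @ beta
    w = np.exp(eta)
    ll, g, H = 0.0, np.zeros(p), np.zeros((p, p))
    for t in np.unique(exit_[event]):
        at_risk = (entry < t) & (exit_ >= t)
        cases = event & (exit_ == t)
        d = cases.sum()
        wr = w[at_risk]
        Zr = Z[at_risk]
        s0 = wr.sum()
        s1 = wr @ Zr
        s2 = (wr[:, None] * Zr).T @ Zr
        m = s1 / s0
        ll += eta[cases].sum() - d * np.log(s0)
        g += Z[cases].sum(axis=0) - d * m
        H += d * (s2 / s0 - np.outer(m, m))
    return ll, g, H


def _fit_one(entry, exit_, event, Z, tol=1e-8, max_iter=50):
    p = Z.shape[1]
    beta = np.zeros(p)
    ll_null = breslow_loglik(beta, entry, exit_, event, Z)
    ll = ll_null
    converged = False
    capped = False
    for _ in range(max_iter):
        ll, g, H = _score_info(beta, entry, exit_, event, Z)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            step = g
        # step halving to guarantee ascent
        new = beta + step
        for _ in range(30):
            if breslow_loglik(new, entry, exit_, event, Z) >= ll:
                break
            step = step / 2.0
            new = beta + step
        beta = new
        if np.any(np.abs(beta) > MAX_ABS_COEF):
            capped = True
            beta = np.clip(beta, -MAX_ABS_COEF, MAX_ABS_COEF)
            warnings.warn(
                "monotone partial likelihood (separation); coefficient capped "
                f"at |beta| = {MAX_ABS_COEF}"
            )
            ll, g, H = _score_info(beta, entry, exit_, event, Z)
            converged = True
            break
    ll, g, H = _score_info(beta, entry, exit_, event, Z)
    with np.errstate(invalid="ignore"):
        try:
            se = np.sqrt(np.diag(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return beta, se, ll, ll_null, converged, capped


def _breslow_baseline(beta, entry, exit_, event, Z, horizon):
    w = np.exp(Z @ beta)
    dA0 = np.zeros(horizon)
    for t in range(1, horizon + 1):
        cases = event & (exit_ == t)
        d = cases.sum()
        if d == 0:
            continue
        at_risk = (entry < t) & (exit_ >= t)
        dA0[t - 1] = d / w[at_risk].sum()
    return dA0


def fit_cause_specific_cox(
    events: pd.DataFrame,
    covariate_names: Optional[List[str]] = None,
    horizon: Optional[int] = None,
) -> CoxFit:
    """Fit one Cox model per permitted transition.

    ``covariate_names`` defaults to every covariate column of the event
    history.  Transitions with no observed events are skipped with a
    warning.  Returns a :class:`CoxFit` with Breslow baseline cumulative
    hazard increments on the daily grid 1..horizon (default: latest exit
    day observed).
    """
    if covariate_names is None:
        covariate_names = covariate_columns(events)
    if horizon is None:
        horizon = int(events["exit_day"].max())
    fit = CoxFit(covariates=list(covariate_names), horizon=horizon)
    for tr in PERMITTED_TRANSITIONS:
        entry, exit_, event, Z = _transition_arrays(events, tr, fit.covariates)
        if event.sum() == 0:
            warnings.warn(f"no events for transition {tr[0]}->{tr[1]}; skipped")
            continue
        beta, se, ll, ll0, conv, capped = _fit_one(entry, exit_, event, Z)
        dA0 = _breslow_baseline(beta, entry, exit_, event, Z, horizon)
        fit.fits[tr] = TransitionFit(
            transition=tr,
            covariates=fit.covariates,
            coef=beta,
            se=se,
            baseline_increments=dA0,
            loglik=ll,
            loglik_null=ll0,
            n_events=int(event.sum()),
            converged=conv,
            capped=capped,
        )
    return fit


def modal_profile(
    events: pd.DataFrame, covariate_names: Optional[List[str]] = None
) -> Dict[str, int]:
    """Most frequent value of each covariate; exact ties resolve to 0."""
    if covariate_names is None:
        covariate_names = covariate_columns(events)
    per_subject = events.groupby("subject_id", sort=False)[list(covariate_names)].first()
    return {c: int(per_subject[c].mean() > 0.5) for c in covariate_names}


def predict_daily_probabilities(
    fit: CoxFit,
    profile: Dict[str, int],
    stratum: Optional[str] = None,
    arm: Optional[str] = None,
    se: Optional[np.ndarray] = None,
) -> DailyTransitionModel:
    """Daily transition matrices for a covariate profile.

    The profile-specific hazard increment for transition i -> j on day t
    is dA0_ij(t) * exp(beta' z).  Increments above 1 are clipped (with a
    warning — possible with tiny risk sets); if the off-diagonal row sum
    still exceeds 1 the row is renormalized projectively.  With all
    coefficients zero this reproduces the nonparametric daily matrices
    exactly.
    """
    if not fit.converged:
        raise ValueError("all transition fits must have converged before prediction")
    missing = [c for c in fit.covariates if c not in profile]
    if missing:
        raise ValueError(f"profile missing covariates: {missing}")
    z = np.array([float(profile[c]) for c in fit.covariates])
    T = fit.horizon
    probs = np.tile(np.eye(_NSTATES), (T, 1, 1))
    se_arr = np.full((T, _NSTATES, _NSTATES), np.nan)
    for (i, j), tf in fit.fits.items():
        h = tf.baseline_increments * np.exp(tf.coef @ z)
        if np.any(h > 1.0):
            warnings.warn(
                f"transition {i}->{j}: hazard increment > 1 clipped to 1"
            )
            h = np.minimum(h, 1.0)
        probs[:, i - 1, j - 1] = h
    for i in (1, 2):
        off = probs[:, i - 1, :].sum(axis=1) - probs[:, i - 1, i - 1]
        over = off > 1.0
        if np.any(over):
            warnings.warn(
                f"state {i}: off-diagonal daily mass > 1 on {over.sum()} day(s); "
                "row renormalized"
            )
            idx = np.where(over)[0]
            for t in idx:
                row = probs[t, i - 1, :].copy()
                row[i - 1] = 0.0
                probs[t, i - 1, :] = row / row.sum()
            off = probs[:, i - 1, :].sum(axis=1) - probs[:, i - 1, i - 1]
        probs[:, i - 1, i - 1] = 1.0 - off
    if se is not None:
        se_arr = se
    model = DailyTransitionModel(
        horizon=T,
        probs=probs,
        se=se_arr,
        provenance="parametric",
        stratum=stratum,
        arm=arm,
    )
    model.validate()
    return model


def parametric_bootstrap_se(
    events: pd.DataFrame,
    profile: Dict[str, int],
    covariate_names: Optional[List[str]] = None,
    horizon: Optional[int] = None,
    n_boot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Subject-level bootstrap SEs of the predicted daily matrices.

    Each replicate resamples subjects, refits every transition model and
    re-predicts for ``profile``; the elementwise standard deviation over
    replicates is returned, shaped like ``DailyTransitionModel.probs``.
    """
    from .multistate import _resample_subjects

    if horizon is None:
        horizon = int(events["exit_day"].max())
    rng = np.random.default_rng(seed)
    reps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            bs = _resample_subjects(events, rng)
            try:
                f = fit_cause_specific_cox(bs, covariate_names, horizon)
                reps.append(predict_daily_probabilities(f, profile).probs)
            except ValueError:
                continue
    return np.asarray(reps).std(axis=0, ddof=1)
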