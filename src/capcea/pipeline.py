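"""End-to-end analysis pipeline.

Chains the stages: simulate (or load) patient event histories, estimate
daily transition models per stratum and arm, attach cost/utility/
transition uncertainty distributions, and run the Markov cost-utility
analysis with probabilistic sensitivity analysis, acceptability curves and
patient-level microsimulation.  Each stage draws its randomness from an
independent substream of a single root seed, recorded in the run metadata.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import cea_engine, cox_transitions, io, multistate, parameters
from .states import ARMS, STRATA
from .synthetic_cohort import default_paper_like_specs, simulate_all

__all__ = ["PipelineResult", "run_pipeline", "spawn_seeds"]


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds from a root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass
class PipelineResult:
    events: pd.DataFrame
    transition_models: Dict[Tuple[str, str], multistate.DailyTransitionModel]
    cea_results: Dict[str, pd.DataFrame]  # per stratum, summarize_psa table
    deterministic: Dict[str, pd.DataFrame]  # per stratum, incremental table
    ceac: Dict[str, pd.DataFrame]
    microsim: Dict[Tuple[str, str], cea_engine.MicrosimResult]
    metadata: dict = field(default_factory=dict)


def estimate_transition_models(
    events: pd.DataFrame,
    horizon: int,
    estimator: str = "nonparametric",
    bootstrap_replicates: int = 200,
    seed: int = 0,
) -> Dict[Tuple[str, str], multistate.DailyTransitionModel]:
    """Per (stratum, arm) daily transition models with standard errors.

    The nonparametric route uses crude daily estimates with binomial SEs;
    the parametric route fits cause-specific Cox models, predicts at the
    modal covariate profile, and attaches subject-level bootstrap SEs.
    """
    if estimator == "nonparametric":
        return multistate.estimate_models_by_group(events, horizon)
    models: Dict[Tuple[str, str], multistate.DailyTransitionModel] = {}
    seeds = iter(spawn_seeds(seed, events.groupby(["stratum", "arm"]).ngroups))
    for (stratum, arm), grp in events.groupby(["stratum", "arm"], sort=False):
        fit = cox_transitions.fit_cause_specific_cox(grp, horizon=horizon)
        profile = cox_transitions.modal_profile(grp)
        se = None
        if bootstrap_replicates > 0:
            se = cox_transitions.parametric_bootstrap_se(
                grp,
                profile,
                horizon=horizon,
                n_boot=bootstrap_replicates,
                seed=next(seeds),
            )
        models[(stratum, arm)] = cox_transitions.predict_daily_probabilities(
            fit, profile, stratum=stratum, arm=arm, se=se
        )
    return models


def run_pipeline(
    cfg: io.RunConfig,
    events: Optional[pd.DataFrame] = None,
    psa_iterations: Optional[int] = None,
) -> PipelineResult:
    """Run the full analysis described by a :class:`~capcea.io.RunConfig`."""
    t0 = time.time()
    seeds = spawn_seeds(cfg.seed, 8)
    if events is None:
        if cfg.event_history is not None:
            events = io.read_event_history(cfg.event_history)
        else:
            specs = default_paper_like_specs(
                ward_total=cfg.ward_total,
                icu_total=cfg.icu_total,
                censor_day=cfg.censor_day,
                frac_stable_at_admission=cfg.frac_stable_at_admission,
                seed=seeds[0],
                with_covariates=cfg.covariates,
            )
            events = simulate_all(specs)
    K = psa_iterations if psa_iterations is not None else cfg.psa_iterations
    models = estimate_transition_models(
        events, cfg.horizon, estimator=cfg.estimator, seed=seeds[1]
    )
    cea_results: Dict[str, pd.DataFrame] = {}
    deterministic: Dict[str, pd.DataFrame] = {}
    ceac_tables: Dict[str, pd.DataFrame] = {}
    microsim: Dict[Tuple[str, str], cea_engine.MicrosimResult] = {}
    psa_seeds = spawn_seeds(seeds[2], len(STRATA))
    ms_seeds = spawn_seeds(seeds[3], len(STRATA) * len(ARMS))
    msk = 0
    for si, stratum in enumerate(STRATA):
        per_arm = {
            arm: models[(stratum, arm)]
            for arm in ARMS
            if (stratum, arm) in models
        }
        if len(per_arm) < len(ARMS):
            warnings.warn(f"stratum {stratum}: missing arms, skipped")
            continue
        pset = parameters.build_parameter_set(stratum, per_arm)
        spec = cea_engine.MarkovSpec(
            stratum=stratum, params=pset, horizon=cfg.horizon
        )
        point = {
            s: (
                (tr := cea_engine.run_cohort(spec, s)).total_cost,
                tr.total_utility,
            )
            for s in spec.strategies
        }
        deterministic[stratum] = cea_engine.incremental_analysis(point)
        if K > 0:
            draws = cea_engine.run_psa(spec, K=K, seed=psa_seeds[si])
            cea_results[stratum] = cea_engine.summarize_psa(draws)
            ceac_tables[stratum] = cea_engine.ceac(
                draws, cea_engine.default_wtp_grid(cfg.wtp_max, cfg.wtp_intervals)
            )
        for arm in ARMS:
            if cfg.microsim_patients > 0:
                microsim[(stratum, arm)] = cea_engine.run_microsimulation(
                    spec, arm, n_patients=cfg.microsim_patients, seed=ms_seeds[msk]
                )
            msk += 1
    meta = dict(
        seed=cfg.seed,
        substreams=seeds,
        horizon=cfg.horizon,
        estimator=cfg.estimator,
        psa_iterations=K,
        microsim_patients=cfg.microsim_patients,
        n_patients=int(events["subject_id"].nunique()),
        elapsed_s=round(time.time() - t0, 2),
    )
    return PipelineResult(
        events=events,
        transition_models=models,
        cea_results=cea_results,
        deterministic=deterministic,
        ceac=ceac_tables,
        microsim=microsim,
        metadata=meta,
    )
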