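# Methods

## State space and time scale

A hospitalization for community-acquired pneumonia is modelled on four
states: **1** admitted on intravenous antibiotics, **2** clinically stable
(switched to oral antibiotics; ICU patients transfer to the ward at this
point), **3** discharged alive, **4** in-hospital death. Permitted moves
are 1→2, 1→3, 1→4 and 2→3; discharge and death are absorbing, and a stable
patient cannot relapse or die in-model. Time is discrete in days: day *t*
is the interval (t−1, t], "at risk just prior to t" means occupying the
state at the start of that interval, and a single categorical draw per day
resolves competing risks without any within-day ordering. Ward and ICU
admissions are analysed as two separate models; the treatment arm
(adherent / over-treated / under-treated empiric antibiotics) indexes the
three strategies compared within each.

## Nonparametric estimation

The cause-specific hazard increment for transition i→j on day t is
dÂᵢⱼ(t) = dᵢⱼ(t)/Yᵢ(t). State-occupation probabilities are the
Aalen–Johansen product-integral P(0,t) = ∏ₛ≤ₜ (I + dÂ(s)); on the daily
grid this is identical to multiplying the daily conditional transition
matrices, so the two outputs are Chapman–Kolmogorov consistent to machine
precision (a property test asserts 1e-12). With no censoring the estimator
equals the empirical state distribution exactly; administrative censoring
(day 30) is the only censoring mechanism modelled.

Conventions for degenerate cells: a day with an empty risk set in a
transient state emits the identity row, flagged and with no standard
error — the only choice that preserves row normalization. Default per-cell
standard errors are binomial, √(p(1−p)/Y); a subject-level bootstrap
(default 500 replicates, seeded) is available for both the occupation
curves and the daily matrices when smoother uncertainty is wanted.

## Cause-specific Cox models

One proportional-hazards model per permitted transition, treating
competing exits from the same origin as censoring, on the
days-since-admission clock with left truncation for sojourns entering a
state after day 0. Covariates are fixed binary baseline indicators; no
time-varying covariates are modelled. Ties — ubiquitous on a daily grid —
use the **Breslow** approximation, chosen because the Breslow baseline
increment at β = 0 equals dᵢⱼ(t)/Yᵢ(t) exactly, so the parametric
predictions reduce to the nonparametric matrices (asserted at 1e-10) and
both routes feed the same product-integral downstream. Estimation is
Newton–Raphson with step halving, converging on a score norm of 1e-8
(≤ 50 iterations); monotone likelihoods are detected by coefficients
escaping ±10 and capped there with a warning. Reported coefficient
standard errors come from the observed information; standard errors of the
*predicted daily matrices* use a subject-level bootstrap with full refits
(default 200 replicates), for uniformity with the nonparametric path.
Predictions use the modal covariate profile (majority value per covariate,
exact ties to 0). Profile hazard increments above 1 are clipped with a
warning, and a row whose off-diagonal mass still exceeds 1 is renormalized
projectively — both only possible with tiny risk sets.

## Cost and utility inputs

All monetary values are 2013 US dollars; no inflation adjustment, no
discounting (the horizon is days, not years), no half-cycle correction.

| input | default | distribution |
|---|---|---|
| ICU bed, day 1 | $5132 (SD $4767) | gamma, method of moments |
| ICU bed, day 8+ | $3825 (SD $2658) | gamma |
| ICU bed, days 2–7 | linear interpolation of mean and SD | gamma |
| ward bed, per day | $1060 (SD $1141) | gamma |
| IV antibiotics, per day | $41.82/64.85/36.57 (ICU), $30.61/43.91/34.97 (ward) for adherent/over/under | fixed scalars |
| oral antibiotics, per day | $12.58/20.50/9.28 (ICU), $14.75/23.10/9.53 (ward) | fixed scalars |
| utility, ICU admission | 0.30 (SD 0.063) | beta, method of moments |
| utility, ward admission | 0.53 (SD 0.10) | beta |
| utility, clinically stable | 0.82 (SD 0.13) | beta |
| utility, discharged / dead | 1 / 0 | degenerate |

The method-of-moments constructors are exact (round-trip to 1e-10):
gamma κ = m²/s², θ = s²/m; beta ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν,
rejecting s² ≥ m(1−m). The day-2–7 ICU interpolation is this package's
choice (only the day-1 and day-8 anchors are published); a full 8-day
schedule can be supplied in config. Drug costs are fixed scalars because
the deterministic sensitivity analysis varies them over grids; they can be
re-derived from a per-patient regimen table and a price CSV via
`mean_daily_drug_cost`. Daily transition cells with probability strictly
inside (0,1) and a usable SE become beta distributions the same way;
degenerate cells stay fixed. Bootstrap SEs can exceed the beta feasibility
bound; such SDs are truncated just inside it with a warning (binomial SEs
never trigger this).

## The Markov engine

The cohort starts entirely in state 1. Accrual timing: costs and utilities
attach to the state occupied *during* cycle t, i.e. after applying that
cycle's matrix, so a patient discharged on day 1 accrues a full horizon of
discharge utility and cumulative utility is bounded by the horizon (14
quality-adjusted life days by default; sensitivity runs extend to 30).
State values per cycle: admitted-ICU = day-indexed ICU bed cost (index =
days spent admitted so far, capped at 8) + IV drugs, utility 0.30;
admitted-ward = ward bed + IV drugs, utility 0.53; stable = ward bed +
oral drugs, utility 0.82 (both strata — stable ICU patients are on the
ward); discharged 0 / 1; dead 0 / 0.

**Microsimulation** samples individual trajectories (default 10,000
patients) under the same accrual rules and mean parameters; its means
agree with the cohort expectation within Monte Carlo error (asserted at
3 SE). Length of stay is the first cycle entering an absorbing state
(horizon if still hospitalized); ICU length of stay is the first cycle out
of the admission state.

**PSA** (default 10,000 iterations; desk-scale runs in this repository use
2000) draws every gamma bed cost (one draw per ICU day index), every beta
utility and every beta transition cell **once per iteration** and applies
it to all cycles — parameter uncertainty, not day-to-day stochastic
variation. Sampled transition rows put the residual mass on the stay
probability; if the sampled off-diagonal mass exceeds 1 the row is
renormalized projectively (stay = 0), preserving relative competing risks.
Cost and utility enter the model linearly, so with transitions fixed the
PSA mean equals the deterministic result up to Monte Carlo error; sampled
transition cells enter multiplicatively and introduce a small Jensen gap.

**Dominance** is strict on cost and weak on utility: a strategy dominates
when it is strictly cheaper and at least as effective as every comparator,
is dominated when some comparator is strictly cheaper and at least as
effective, and is otherwise a trade-off (identical strategies are
trade-offs). The weak-utility side keeps pure cost differences decisive
when transition structures tie, which the deterministic grids require;
incremental cost-utility ratios are reported only for trade-offs. The
**CEAC** records, per willingness-to-pay λ on the grid $0–$1000/QALD in 20
intervals (= $0–$365,000/QALY), the fraction of iterations each strategy
maximizes net monetary benefit λ·utility − cost; exact ties resolve to the
lower cost, then alphabetically. **Deterministic grids** (`dsa_grid`) fix
named parameters (per-arm drug costs, flat bed costs, state utilities) on
a cartesian grid with both endpoints included and report the dominant
strategy or "none" per point.

Seeding: one root seed spawns independent substreams (cohort simulation,
estimation bootstrap, PSA per stratum, microsimulation per arm) via
`numpy.random.SeedSequence`; substreams are recorded in run metadata and
identical seeds give byte-identical outputs.

## The synthetic cohort generator

The source patient-level cohort is available only on request, so the
generator emulates its structure: two strata with the published sizes and
arm splits (ward 877/167/394; ICU 98/28/71 — scalable to any total),
ten binary baseline covariates drawn independently at prevalences whose
modal profile matches the published one (severe disease present,
complications absent, early antimicrobials and vaccination absent,
cultures and oxygen assessment done), optional log-linear covariate
effects on the hazards (giving the Cox stage a known truth to recover),
2% of subjects clinically stable at admission (the source says only "a
small number"; exposed in config), and administrative censoring at day 30.

Default hazards are constant over days and were calibrated analytically
(forward matrix products, no simulation) to reproduce the published
length-of-stay medians exactly — ward overall 8/10/9 days and ICU
admission-state 12/4/8 days for adherent/over/under, ICU overall
14/11/14 — and the published *orderings* of 7-day stability, 14-day
mortality and 14-day discharge in both strata:

| stratum/arm | 1→2 | 1→3 | 1→4 | 2→3 |
|---|---|---|---|---|
| ward adherent | 0.180 | 0.010 | 0.012 | 0.220 |
| ward over | 0.110 | 0.008 | 0.022 | 0.155 |
| ward under | 0.125 | 0.008 | 0.020 | 0.190 |
| ICU adherent | 0.042 | 0.004 | 0.012 | 0.380 |
| ICU over | 0.132 | 0.002 | 0.031 | 0.105 |
| ICU under | 0.045 | 0.005 | 0.038 | 0.078 |

Constant hazards cannot reproduce every published marginal simultaneously
(the real hazards are time-varying), so absolute levels of some marginals
are compressed — e.g. the ICU adherent 7-day stability probability is 0.25
here versus 0.40 in the source — while every cross-arm ordering is
preserved. What passing tests therefore show is that the *pipeline*
recovers whatever structure generated the data and that the decision
model's directions follow from that structure; they do not re-establish
the source study's absolute cost levels, which depended on the real
cohort's hazard trajectories.

## Problem sizes and runtime

Unit and property tests use cohorts of 40–2000 subjects; recovery suites
use n = 2000 (hazards, Aalen–Johansen, Cox point estimates) and 50
replicates of n = 500 (Cox coverage). End-to-end runs use the source-study
cohort sizes (1438 ward / 197 ICU), a 14-day horizon, 2000 PSA iterations
and 10,000 microsimulation patients. The full test suite runs in well
under a minute; the acceptance script in about a second.

## Known limitations

- The 28-patient ICU over-treated arm makes that stratum's daily estimates
  noisy; the dominance direction reproduces in ~19/20 generator seeds at
  the default sizes. (The source study flags the same 28-patient
  limitation.)
- PSA dispersion on synthetic cohorts is much smaller than the published
  percentile intervals, so acceptance fractions near the winner approach
  1.0 rather than the published 42–64%: binomial cell SEs on a cleanly
  generated cohort understate the real cohort's parameter uncertainty.
- No post-discharge or long-term modelling, no readmission, no
  antimicrobial-resistance costs; utilities are independent of treatment
  arm; states 3 and 4 are strictly absorbing within the horizon.
- "Time-dependent" Cox modelling is read as cause-specific Cox on the
  admission clock with fixed baseline covariates; no time-varying
  covariates or coefficients.
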