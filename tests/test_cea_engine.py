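"""Markov engine: accrual arithmetic, microsimulation, PSA, CEAC, DSA."""

import numpy as np
import pandas as pd
import pytest

from capcea.cea_engine import (
    MarkovSpec,
    PSADraws,
    ceac,
    default_wtp_grid,
    dsa_grid,
    incremental_analysis,
    run_cohort,
    run_microsimulation,
    run_psa,
    summarize_psa,
)
from capcea.multistate import DailyTransitionModel
from capcea.parameters import build_parameter_set

T = 14
WARD_C1 = 1060.0 + 30.61  # bed + adherent IV drugs
U_WARD = 0.53


def model_from_matrix(P, T=T, se=None):
    probs = np.tile(np.asarray(P, dtype=float), (T, 1, 1))
    se_arr = np.full((T, 4, 4), np.nan) if se is None else se
    return DailyTransitionModel(horizon=T, probs=probs, se=se_arr,
                                provenance="nonparametric")


IDENTITY = np.eye(4)
DISCHARGE_NOW = np.array([
    [0, 0, 1, 0],
    [0, 0, 1, 0],
    [0, 0, 1, 0],
    [0, 0, 0, 1],
], dtype=float)
HALF_DISCHARGE = np.array([
    [0.5, 0, 0.5, 0],
    [0, 1, 0, 0],
    [0, 0, 1, 0],
    [0, 0, 0, 1],
], dtype=float)


def ward_spec(mats, horizon=T):
    """Ward spec where all three arms share the same transition matrix."""
    models = {arm: model_from_matrix(m, T=horizon)
              for arm, m in mats.items()}
    pset = build_parameter_set("ward", models)
    return MarkovSpec(stratum="ward", params=pset, horizon=horizon)


class TestRunCohort:
    def test_identity_transitions_closed_form(self):
        spec = ward_spec({a: IDENTITY for a in ("adherent", "over", "under")})
        trace = run_cohort(spec, "adherent")
        assert trace.total_cost == pytest.approx(T * WARD_C1)
        assert trace.total_utility == pytest.approx(T * U_WARD)

    def test_immediate_discharge_full_utility(self):
        spec = ward_spec({a: DISCHARGE_NOW for a in ("adherent", "over", "under")})
        trace = run_cohort(spec, "adherent")
        assert trace.total_utility == pytest.approx(float(T))
        assert trace.total_cost == pytest.approx(0.0)

    def test_two_cycle_toy_matches_path_enumeration(self):
        """Horizon 2 with P(1->3) = 0.5 per cycle: enumerate the three
        paths (discharged cycle 1 / cycle 2 / never) by hand."""
        spec = ward_spec({a: HALF_DISCHARGE for a in ("adherent", "over", "under")},
                         horizon=2)
        trace = run_cohort(spec, "adherent")
        u = 0.5 * 2.0 + 0.25 * (U_WARD + 1.0) + 0.25 * (2 * U_WARD)
        c = 0.25 * WARD_C1 + 0.25 * 2 * WARD_C1
        assert trace.total_utility == pytest.approx(u)
        assert trace.total_cost == pytest.approx(c)

    def test_occupation_conserved_every_cycle(self):
        P = np.array([
            [0.6, 0.25, 0.1, 0.05],
            [0, 0.7, 0.3, 0],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ])
        spec = ward_spec({a: P for a in ("adherent", "over", "under")})
        trace = run_cohort(spec, "adherent")
        np.testing.assert_allclose(trace.occupation.sum(axis=1), 1.0, atol=1e-12)
        assert 0.0 <= trace.total_utility <= T

    def test_icu_day_indexed_bed_cost(self):
        models = {a: model_from_matrix(IDENTITY) for a in ("adherent", "over", "under")}
        pset = build_parameter_set("icu", models)
        spec = MarkovSpec(stratum="icu", params=pset, horizon=T)
        trace = run_cohort(spec, "adherent")
        sched = [pset.cost.icu_day(t).mean for t in range(1, T + 1)]
        assert trace.total_cost == pytest.approx(sum(sched) + T * 41.82)
        assert sched[0] == pytest.approx(5132.0)
        assert sched[-1] == pytest.approx(3825.0)


class TestMicrosimulation:
    def test_agrees_with_cohort_expectation(self):
        P = np.array([
            [0.6, 0.25, 0.1, 0.05],
            [0, 0.7, 0.3, 0],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ])
        spec = ward_spec({a: P for a in ("adherent", "over", "under")})
        trace = run_cohort(spec, "adherent")
        ms = run_microsimulation(spec, "adherent", n_patients=10_000, seed=4)
        for sample, expected in [(ms.cost, trace.total_cost),
                                 (ms.utility, trace.total_utility)]:
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - expected) < 3 * se

    def test_identity_transitions_deterministic_patients(self):
        spec = ward_spec({a: IDENTITY for a in ("adherent", "over", "under")})
        ms = run_microsimulation(spec, "adherent", n_patients=500, seed=1)
        assert np.ptp(ms.cost) == 0.0
        assert np.ptp(ms.utility) == 0.0

    def test_seeded_runs_identical(self):
        spec = ward_spec({a: HALF_DISCHARGE for a in ("adherent", "over", "under")})
        a = run_microsimulation(spec, "adherent", n_patients=2000, seed=9)
        b = run_microsimulation(spec, "adherent", n_patients=2000, seed=9)
        np.testing.assert_array_equal(a.cost, b.cost)
        assert a.median_los == b.median_los


def spec_with_uncertainty(se_val=0.04):
    P = np.array([
        [0.6, 0.25, 0.1, 0.05],
        [0, 0.7, 0.3, 0],
        [0, 0, 1, 0],
        [0, 0, 0, 1],
    ])
    se = np.full((T, 4, 4), np.nan)
    for j in (1, 2, 3):
        se[:, 0, j] = se_val
    se[:, 1, 2] = se_val
    models = {a: model_from_matrix(P, se=se.copy())
              for a in ("adherent", "over", "under")}
    pset = build_parameter_set("ward", models)
    return MarkovSpec(stratum="ward", params=pset, horizon=T)


class TestPSA:
    def test_fixed_transitions_mean_matches_cohort(self):
        """With transitions fixed, PSA mean cost/utility equals the
        deterministic cohort result up to Monte Carlo error (cost and
        utility enter linearly, so no Jensen gap)."""
        spec = ward_spec({a: HALF_DISCHARGE for a in ("adherent", "over", "under")})
        trace = run_cohort(spec, "adherent")
        draws = run_psa(spec, K=4000, seed=2)
        c = draws.pivot("cost")["adherent"]
        u = draws.pivot("utility")["adherent"]
        assert abs(c.mean() - trace.total_cost) < 3 * c.std() / np.sqrt(len(c))
        assert abs(u.mean() - trace.total_utility) < 3 * u.std() / np.sqrt(len(u))

    def test_sampled_rows_remain_distributions(self):
        spec = spec_with_uncertainty()
        draws = run_psa(spec, K=200, seed=3)
        assert np.isfinite(draws.draws["cost"]).all()
        assert draws.draws["utility"].between(0, T).all()

    def test_interval_widens_with_doubled_cost_sd(self):
        from capcea.parameters import CostModel, gamma_from_moments, icu_cost_schedule
        import capcea.parameters as prm

        def width(sd):
            models = {a: model_from_matrix(HALF_DISCHARGE)
                      for a in ("adherent", "over", "under")}
            cost = CostModel(
                icu_daily=icu_cost_schedule(),
                ward_daily=gamma_from_moments(1060.0, sd),
                drug_iv_daily=dict(prm.DRUG_IV_DAILY),
                drug_oral_daily=dict(prm.DRUG_ORAL_DAILY),
            )
            pset = build_parameter_set("ward", models, cost=cost)
            spec = MarkovSpec(stratum="ward", params=pset, horizon=T)
            c = run_psa(spec, K=2000, seed=5).pivot("cost")["adherent"]
            return c.quantile(0.975) - c.quantile(0.025)

        assert width(2 * 1141.0) > width(1141.0)

    def test_psa_reproducible(self):
        spec = spec_with_uncertainty()
        a = run_psa(spec, K=100, seed=11).draws
        b = run_psa(spec, K=100, seed=11).draws
        pd.testing.assert_frame_equal(a, b)


class TestIncrementalAnalysis:
    def test_published_means_give_printed_increment(self):
        res = incremental_analysis({
            "adherent": (10156.0, 11.2),
            "over": (11535.0, 10.1),
            "under": (10954.0, 10.5),
        })
        assert res.loc["over", "incremental_cost"] == pytest.approx(1379.0)
        assert res.loc["adherent", "dominance"] == "dominant"

    def test_identical_strategies_zero_increment(self):
        res = incremental_analysis({"adherent": (5.0, 1.0), "over": (5.0, 1.0)})
        assert res.loc["over", "incremental_cost"] == 0.0
        assert res.loc["over", "incremental_utility"] == 0.0
        assert (res["dominance"] == "trade-off").all()

    def test_dominance_by_definition(self):
        res = incremental_analysis(
            {"adherent": (100.0, 10.0), "over": (90.0, 11.0)}
        )
        assert res.loc["over", "dominance"] == "dominant"
        assert res.loc["adherent", "dominance"] == "dominated"

    def test_missing_base_rejected(self):
        with pytest.raises(ValueError):
            incremental_analysis({"over": (1.0, 1.0)}, base="adherent")

    def test_icer_only_for_trade_offs(self):
        res = incremental_analysis({
            "adherent": (100.0, 10.0),
            "over": (150.0, 12.0),   # dearer and better: trade-off
            "under": (120.0, 9.0),   # dearer and worse: dominated
        })
        assert res.loc["over", "icer"] == pytest.approx(50.0 / 2.0)
        assert np.isnan(res.loc["under", "icer"])


def _draws(rows):
    df = pd.DataFrame(rows, columns=["iteration", "strategy", "cost", "utility"])
    return PSADraws(draws=df, strategies=sorted(df["strategy"].unique()))


class TestCEAC:
    def test_fractions_sum_to_one_and_endpoints(self):
        spec = spec_with_uncertainty()
        draws = run_psa(spec, K=500, seed=7)
        curve = ceac(draws)
        assert curve.index[0] == 0.0 and curve.index[-1] == 1000.0
        assert len(curve) == 21
        np.testing.assert_allclose(curve.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_wtp_equals_cheapest_fractions(self):
        spec = spec_with_uncertainty()
        draws = run_psa(spec, K=500, seed=8)
        curve = ceac(draws)
        c = draws.pivot("cost")
        cheapest = c.idxmin(axis=1).value_counts(normalize=True)
        for s in curve.columns:
            assert curve.loc[0.0, s] == pytest.approx(cheapest.get(s, 0.0))

    def test_hand_enumerated_iterations(self):
        rows = [
            (0, "a", 100.0, 1.0), (0, "b", 150.0, 2.0),
            (1, "a", 100.0, 1.0), (1, "b", 90.0, 0.5),
            (2, "a", 200.0, 1.0), (2, "b", 150.0, 1.2),
        ]
        curve = ceac(_draws(rows), wtp_grid=[100.0])
        # NMB at 100: it0 a=0,b=50 -> b; it1 a=0,b=-40 -> a; it2 a=-100,b=-30 -> b
        assert curve.loc[100.0, "b"] == pytest.approx(2 / 3)
        assert curve.loc[100.0, "a"] == pytest.approx(1 / 3)

    def test_uniform_dominance_accepted_everywhere(self):
        rows = []
        for k in range(5):
            rows += [(k, "a", 100.0 + k, 2.0), (k, "b", 150.0 + k, 1.0)]
        curve = ceac(_draws(rows))
        assert (curve["a"] == 1.0).all()

    def test_exact_tie_goes_to_lower_cost(self):
        rows = [(0, "a", 100.0, 1.0), (0, "b", 90.0, 1.0)]
        curve = ceac(_draws(rows), wtp_grid=[50.0])
        # equal utility: at any wtp b has higher NMB... make NMB tie exactly
        rows = [(0, "a", 100.0, 2.0), (0, "b", 90.0, 1.8)]
        curve = ceac(_draws(rows), wtp_grid=[50.0])  # NMB: a=0, b=0
        assert curve.loc[50.0, "b"] == 1.0


class TestDSAGrid:
    def test_grid_endpoints_and_size(self):
        spec = ward_spec({a: IDENTITY for a in ("adherent", "over", "under")})
        grid = dsa_grid(spec, [("iv_cost:adherent", (1.0, 100.0), 20)])
        assert len(grid) == 21
        assert grid["iv_cost:adherent"].iloc[0] == 1.0
        assert grid["iv_cost:adherent"].iloc[-1] == 100.0

    def test_cheapest_drug_dominant_when_only_drug_costs_differ(self):
        spec = ward_spec({a: IDENTITY for a in ("adherent", "over", "under")})
        grid = dsa_grid(spec, [("iv_cost:adherent", (1.0, 20.0), 5)])
        # adherent IV of at most $20 always undercuts over ($43.91) and
        # under ($34.97); transitions identical so utilities tie
        assert (grid["dominant"] == "adherent").all()

    def test_two_axis_crossover_at_closed_form_threshold(self):
        """All-identity transitions: totals are linear in drug cost, so the
        dominance boundary sits exactly where daily IV costs cross."""
        spec = ward_spec({a: IDENTITY for a in ("adherent", "over", "under")})
        grid = dsa_grid(
            spec,
            [("iv_cost:adherent", (0.0, 60.0), 6), ("iv_cost:over", (30.0, 30.0), 0)],
        )
        for _, row in grid.iterrows():
            adh = row["iv_cost:adherent"]
            if adh < 30.0:  # under is fixed at $34.97
                assert row["dominant"] == "adherent"
            elif adh == 30.0:
                assert row["dominant"] == "none"
            else:
                assert row["dominant"] == "over"

    def test_unknown_parameter_rejected(self):
        spec = ward_spec({a: IDENTITY for a in ("adherent", "over", "under")})
        with pytest.raises(ValueError, match="unknown sensitivity parameter"):
            dsa_grid(spec, [("bogus", (0.0, 1.0), 2)])


def test_summarize_psa_intervals_and_increments():
    spec = spec_with_uncertainty()
    draws = run_psa(spec, K=400, seed=12)
    table = summarize_psa(draws)
    assert set(table.index) == {"adherent", "over", "under"}
    assert (table["cost_lo"] <= table["cost"]).all()
    assert (table["cost"] <= table["cost_hi"]).all()
    assert table.loc["adherent", "incremental_cost"] == 0.0


def test_wtp_grid_convention():
    grid = default_wtp_grid(1000.0, 20)
    assert len(grid) == 21
    assert grid[0] == 0.0 and grid[-1] == 1000.0
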