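"""Decision tree, transition logic, and the lifetime cohort engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baocea.markov import (DEAD, STRATEGY_BMC, STRATEGY_EVT, SubCohort,
                           build_subcohorts, evaluate_strategy,
                           first_cycle_accounting, recurrence_probability,
                           run_cohort, transition_row)
from baocea.params import LifeTable, OutcomeDistribution, ParameterError


def immortal_params(ref_params, **kw):
    """Parameters with no background death and no recurrence (identity dynamics)."""
    defaults = dict(death_hr_by_mrs=(1e-12,) * 6,
                    p_recurrence_by_year=(0.0,) * 10)
    defaults.update(kw)
    return ref_params.replace(**defaults)


@pytest.fixture(scope="module")
def no_death_lt():
    # near-zero mortality until the terminal age
    ages = tuple(range(0, 121))
    return LifeTable(ages=ages, qx=(0.0,) * 120 + (1.0,))


class TestDecisionTree:
    def test_evt_leaf_weights(self, ref_params):
        leaves = {sc.label: sc for sc in build_subcohorts(STRATEGY_EVT, ref_params)}
        assert leaves["stenosis_stented"].weight == pytest.approx(0.245346, abs=1e-12)
        assert leaves["stenosis_no_stent"].weight == pytest.approx(0.397 * 0.382)
        assert sum(sc.weight for sc in leaves.values()) == pytest.approx(1.0, abs=1e-12)

    def test_bmc_weights_sum_to_one(self, ref_params):
        leaves = build_subcohorts(STRATEGY_BMC, ref_params)
        assert len(leaves) == 2
        assert sum(sc.weight for sc in leaves) == pytest.approx(1.0, abs=1e-12)

    def test_no_stenosis_degenerate_tree(self, ref_params):
        p = ref_params.replace(p_stenosis=0.0)
        for strategy in (STRATEGY_EVT, STRATEGY_BMC):
            leaves = build_subcohorts(strategy, p)
            assert len(leaves) == 1
            assert leaves[0].weight == 1.0 and not leaves[0].stenosis

    def test_stent_requires_evt_with_stenosis(self):
        with pytest.raises(ParameterError):
            SubCohort(STRATEGY_BMC, False, True, 0.5)

    def test_multipliers(self, ref_params):
        stented = build_subcohorts(STRATEGY_EVT, ref_params)[0]
        ratios = [a.ratio for a in stented.recurrence_multipliers]
        assert ratios == [3.4, 1.057]
        plain = build_subcohorts(STRATEGY_EVT, ref_params)[2]
        assert plain.recurrence_multipliers == ()


class TestRecurrence:
    def test_published_year1(self, ref_params):
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[1]  # no stenosis
        assert recurrence_probability(1, sc, ref_params) == 0.059

    def test_stenosis_risk_ratio(self, ref_params):
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[0]
        assert recurrence_probability(1, sc, ref_params) == pytest.approx(0.2006)

    def test_hold_last_value_beyond_year10(self, ref_params):
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[1]
        assert recurrence_probability(25, sc, ref_params) == 0.016


class TestTransitionRow:
    def test_dead_is_absorbing(self, ref_params, life_table):
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[1]
        row = transition_row(DEAD, 70, 3, sc, ref_params, life_table)
        assert list(row) == [0, 0, 0, 0, 0, 0, 1]

    def test_identity_without_death_or_recurrence(self, ref_params, no_death_lt):
        p = immortal_params(ref_params)
        sc = build_subcohorts(STRATEGY_BMC, p)[0]
        for s in range(6):
            row = transition_row(s, 70, 2, sc, p, no_death_lt)
            assert row[s] == pytest.approx(1.0, abs=1e-9)

    def test_certain_recurrence_worse_of_rule(self, ref_params, no_death_lt):
        # from mRS4 a recurrent stroke in categories mRS0-1..4 leaves the
        # patient at mRS4 (0.129+0.136+0.164+0.247 = 0.676); 0.135 -> mRS5,
        # 0.189 -> Dead
        p = immortal_params(ref_params,
                            p_recurrence_by_year=(1.0,) * 10,
                            rr_recurrence_stenosis=1.0)
        sc = build_subcohorts(STRATEGY_BMC, p)[1]
        row = transition_row(4, 70, 1, sc, p, no_death_lt)
        assert row[4] == pytest.approx(0.676, abs=1e-9)
        assert row[5] == pytest.approx(0.135, abs=1e-9)
        assert row[DEAD] == pytest.approx(0.189, abs=1e-9)

    def test_mrs01_mapping_variants(self, ref_params, no_death_lt):
        base = dict(p_recurrence_by_year=(1.0,) * 10, rr_recurrence_stenosis=1.0)
        for mapping, expect0 in (("mrs1", 0.0), ("mrs0", 0.129), ("split", 0.0645)):
            p = immortal_params(ref_params, recurrent_mrs01_mapping=mapping, **base)
            sc = build_subcohorts(STRATEGY_BMC, p)[1]
            row = transition_row(0, 70, 1, sc, p, no_death_lt)
            assert row[0] == pytest.approx(expect0, abs=1e-12)

    @given(state=st.integers(0, 5), age=st.integers(50, 109),
           year=st.integers(1, 40), hr=st.floats(0.5, 6.0),
           rec=st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_to_one(self, state, age, year, hr, rec, ref_params, life_table):
        p = ref_params.replace(death_hr_by_mrs=(hr,) * 6,
                               p_recurrence_by_year=(rec,) * 10)
        for sc in build_subcohorts(STRATEGY_EVT, p):
            row = transition_row(state, age, year, sc, p, life_table)
            assert abs(row.sum() - 1.0) < 1e-12
            assert (row >= 0).all()


class TestFirstCycle:
    def test_all_dead_entry_on_stented_leaf(self, ref_params):
        sc = build_subcohorts(STRATEGY_EVT, ref_params)[0]
        entry = OutcomeDistribution((0, 0, 0, 0, 0, 0, 1.0))
        cost, qaly, post = first_cycle_accounting(entry, sc, ref_params)
        assert cost == pytest.approx(88_159 + 17_103 + 9_000)
        assert qaly == 0.0
        assert post[DEAD] == 1.0

    def test_all_mrs0_entry_on_bmc(self, ref_params):
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[1]
        entry = OutcomeDistribution((1.0, 0, 0, 0, 0, 0, 0))
        cost, qaly, post = first_cycle_accounting(entry, sc, ref_params)
        assert cost == pytest.approx(26_705 + 15_213 + 24_988)
        assert qaly == pytest.approx(1.0)
        assert post[0] == 1.0


class TestRunCohort:
    def test_pure_survival_qalys(self, ref_params, no_death_lt):
        p = immortal_params(ref_params, utilities=(1.0,) * 6, discount_rate=0.0,
                            start_age=66)
        sc = build_subcohorts(STRATEGY_BMC, p)[1]
        trace = run_cohort(sc, p, no_death_lt, horizon=10)
        alive = 1.0 - p.entry_dist_bmc.p[6]
        assert trace.total_qaly == pytest.approx(10.0 * alive, abs=1e-9)

    def test_discount_factor_cycle2(self, ref_params, life_table):
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[1]
        trace = run_cohort(sc, ref_params, life_table, horizon=5)
        assert trace.discount_factors[1] == pytest.approx(1 / 1.03, abs=1e-9)
        assert trace.discount_factors[0] == 1.0

    def test_mrs5_long_term_cost(self, ref_params, no_death_lt):
        p = immortal_params(ref_params,
                            entry_dist_bmc=OutcomeDistribution((0, 0, 0, 0, 0, 1.0, 0)),
                            discount_rate=0.0)
        sc = build_subcohorts(STRATEGY_BMC, p)[1]
        trace = run_cohort(sc, p, no_death_lt, horizon=5)
        assert np.allclose(trace.qaly_cycle, 0.0)
        assert np.allclose(trace.cost_cycle[1:], 86_612.0)

    def test_mass_conservation_and_absorbing_death(self, ref_params, life_table):
        for strategy in (STRATEGY_BMC, STRATEGY_EVT):
            for sc in build_subcohorts(strategy, ref_params):
                trace = run_cohort(sc, ref_params, life_table)
                totals = trace.occupancy.sum(axis=1)
                assert np.allclose(totals, 1.0, atol=1e-9)
                dead = trace.occupancy[:, DEAD]
                assert (np.diff(dead) >= -1e-12).all()
                assert (trace.qaly_cycle >= 0).all()
                alive = trace.occupancy[:, :6].sum(axis=1)
                assert (trace.qaly_cycle <= alive + 1e-12).all()

    def test_zero_utilities_zero_qalys(self, ref_params, life_table):
        p = ref_params.replace(utilities=(0.0,) * 6)
        sc = build_subcohorts(STRATEGY_EVT, p)[2]
        assert run_cohort(sc, p, life_table).total_qaly == 0.0

    def test_undiscounted_totals_dominate_discounted(self, ref_params, life_table):
        sc = build_subcohorts(STRATEGY_EVT, ref_params)[2]
        trace = run_cohort(sc, ref_params, life_table)
        assert trace.total_cost_undiscounted >= trace.total_cost
        assert trace.total_qaly_undiscounted >= trace.total_qaly

    def test_life_table_not_covering_start_age(self, ref_params):
        lt = LifeTable(ages=(0, 1, 2), qx=(0.01, 0.01, 1.0))
        sc = build_subcohorts(STRATEGY_BMC, ref_params)[1]
        with pytest.raises(ParameterError, match="life table"):
            run_cohort(sc, ref_params, lt)


class TestEvaluateStrategy:
    def test_weighted_mean_of_single_leaf(self, ref_params, life_table):
        p = ref_params.replace(p_stenosis=0.0)
        res = evaluate_strategy(STRATEGY_BMC, p, life_table)
        assert len(res.leaves) == 1
        assert res.cost == pytest.approx(res.leaves[0].cost)
        assert res.qaly == pytest.approx(res.leaves[0].qaly)

    def test_strategy_equals_weight_sum_of_leaves(self, ref_params, life_table):
        res = evaluate_strategy(STRATEGY_EVT, ref_params, life_table)
        cost = sum(l.subcohort.weight * l.cost for l in res.leaves)
        assert res.cost == pytest.approx(cost, abs=1e-9)

    def test_evt_addon_shifts_strategy_cost_exactly(self, ref_params, life_table):
        base = evaluate_strategy(STRATEGY_EVT, ref_params, life_table).cost
        bumped = evaluate_strategy(
            STRATEGY_EVT, ref_params.replace(cost_evt_addon=17_103 + 500.0),
            life_table).cost
        assert bumped - base == pytest.approx(500.0, abs=1e-6)
        # BMC never pays the procedure
        assert evaluate_strategy(
            STRATEGY_BMC, ref_params.replace(cost_evt_addon=99_999.0),
            life_table).cost == pytest.approx(
                evaluate_strategy(STRATEGY_BMC, ref_params, life_table).cost)
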