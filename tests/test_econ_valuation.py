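"""Economic valuation: dosing, discounting, ledgers, ICER and dominance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from nsclc_cea import (
    CohortTrace,
    CostInputs,
    CycleSettings,
    Dominance,
    DrugComponent,
    RegimenSpec,
    UtilityInputs,
    ae_burden,
    compare_strategies,
    cycle_drug_cost,
    discount_factor,
    evaluate_strategy,
)
from nsclc_cea.econ_valuation import relative_price_reduction
from nsclc_cea.markov_engine import PFS_ON


def constant_pfs_trace(n):
    """Whole cohort parked in PFS_ON for n cycles (no transitions)."""
    occ = np.zeros((n + 1, 4))
    occ[:, PFS_ON] = 1.0
    return CohortTrace(occ, np.zeros(n), np.zeros(n))


class TestDrugCosts:
    def test_flat_dose_vial_count(self):
        reg = RegimenSpec((DrugComponent("tislelizumab", "flat", 200, 100, 338.0),))
        assert cycle_drug_cost(reg) == pytest.approx(676.0)

    def test_calvert_formula_dose(self):
        comp = DrugComponent("carboplatin", "calvert_auc", 5, 50, 10.0)
        reg = RegimenSpec((comp,), crcl=70.0)
        # dose 5 * (70 + 25) = 475 mg -> 10 units of 50 mg
        assert cycle_drug_cost(reg) == pytest.approx(100.0)

    def test_per_m2_dose_and_vial_rounding(self):
        comp = DrugComponent("pemetrexed", "per_m2", 500, 500, 124.0)
        rounded = RegimenSpec((comp,), bsa=1.72)
        exact = RegimenSpec((comp,), bsa=1.72, vial_rounding=False)
        assert cycle_drug_cost(rounded) == pytest.approx(2 * 124.0)  # 860 mg -> 2 vials
        assert cycle_drug_cost(exact) == pytest.approx(860 / 500 * 124.0)

    def test_zero_priced_regimen(self):
        reg = RegimenSpec((DrugComponent("placebo", "flat", 100, 100, 0.0),))
        assert cycle_drug_cost(reg) == 0.0

    def test_max_cycles_cap(self):
        comp = DrugComponent("carboplatin", "calvert_auc", 5, 100, 9.0, max_cycles=4)
        reg = RegimenSpec((comp,))
        assert cycle_drug_cost(reg, cycle=3) > 0
        assert cycle_drug_cost(reg, cycle=4) == 0.0


class TestAEBurden:
    def test_weighted_sum(self):
        assert ae_burden([(0.1, 0.05), (0.2, 0.10)]) == pytest.approx(0.025)

    def test_empty_and_degenerate(self):
        assert ae_burden([]) == 0.0
        assert ae_burden([(1.0, 3.0), (1.0, 4.0)]) == pytest.approx(7.0)

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1e4)), max_size=8))
    @hyp_settings(max_examples=50, deadline=None)
    def test_bounded_by_plain_sum(self, pairs):
        assert 0.0 <= ae_burden(pairs) <= sum(v for _, v in pairs) + 1e-9


class TestDiscounting:
    def test_no_elapsed_time(self):
        assert discount_factor(0, CycleSettings(21, 20), 0.05) == 1.0

    def test_closed_form_at_cycle_100(self):
        f = discount_factor(100, CycleSettings(21, 20), 0.05)
        assert f == pytest.approx(1.05 ** (-100 * 21 / 365.25), abs=1e-12)
        assert f == pytest.approx(0.7554, abs=1e-4)

    def test_zero_rate(self):
        assert discount_factor(500, CycleSettings(21, 20), 0.0) == 1.0


def toy_inputs(cost_per_cycle=100.0, u=1.0, discount=0.0):
    reg = RegimenSpec((DrugComponent("drug", "flat", 100, 100, cost_per_cycle),))
    costs = CostInputs(regimens={"A": reg}, discount_annual=discount)
    utils = UtilityInputs(u_pfs=u, u_pd=u)
    return costs, utils


class TestEvaluateStrategy:
    def test_constant_reward_closed_form(self):
        # 10 cycles, no discounting, no half-cycle correction
        n = 10
        settings = CycleSettings(21, n * 21 / 365.25, half_cycle_correction=False)
        costs, utils = toy_inputs()
        res = evaluate_strategy(constant_pfs_trace(n), costs, utils, settings, "A")
        assert res.total_cost == pytest.approx(1000.0, abs=1e-8)
        assert res.total_qalys == pytest.approx(10 * 21 / 365.25, abs=1e-8)
        assert res.total_qalys == pytest.approx(0.5749, abs=1e-4)

    def test_geometric_discounting_closed_form(self):
        n = 50
        settings = CycleSettings(21, n * 21 / 365.25, half_cycle_correction=False)
        costs, utils = toy_inputs(discount=0.05)
        res = evaluate_strategy(constant_pfs_trace(n), costs, utils, settings, "A")
        r = 1.05 ** (-21 / 365.25)
        assert res.total_cost == pytest.approx(100 * (1 - r**n) / (1 - r), abs=1e-8)

    def test_zero_utilities_annihilate_qalys(self):
        n = 8
        settings = CycleSettings(21, n * 21 / 365.25, half_cycle_correction=False)
        costs, utils = toy_inputs(u=0.0)
        res = evaluate_strategy(constant_pfs_trace(n), costs, utils, settings, "A")
        assert res.total_qalys == 0.0

    def test_cost_homogeneity_degree_one(self):
        # doubling every monetary input doubles total cost, QALYs unchanged
        n = 12
        settings = CycleSettings(21, n * 21 / 365.25, half_cycle_correction=False)
        trace = constant_pfs_trace(n)

        def run(scale):
            reg = RegimenSpec(
                (DrugComponent("drug", "flat", 100, 100, scale * 250.0),),
                premedication_per_cycle=scale * 15.0,
            )
            costs = CostInputs(
                regimens={"A": reg},
                ae_costs={"A": ((0.3, scale * 600.0),)},
                followup_per_cycle=scale * 92.0,
                bsc_per_cycle=scale * 150.0,
                subsequent_therapy_per_cycle=scale * 580.0,
                p_subsequent={"A": 0.5},
                end_of_life_onetime=scale * 1869.0,
                discount_annual=0.05,
            )
            return evaluate_strategy(trace, costs, UtilityInputs(), settings, "A")

        one, two = run(1.0), run(2.0)
        assert two.total_cost == pytest.approx(2 * one.total_cost, rel=1e-12)
        assert two.total_qalys == pytest.approx(one.total_qalys, rel=1e-12)

    def test_ledgers_sum_to_totals(self, model):
        pair = model.evaluate()
        for res in (pair.intervention, pair.control):
            assert sum(v.sum() for v in res.cost_ledger.values()) == pytest.approx(
                res.total_cost, abs=1e-6)
            assert sum(v.sum() for v in res.qaly_ledger.values()) == pytest.approx(
                res.total_qalys, abs=1e-6)

    def test_qalys_below_life_years_below_horizon(self, model):
        pair = model.evaluate()
        for res in (pair.intervention, pair.control):
            assert res.total_qalys <= res.total_life_years <= 20.0
        undisc = model.evaluate({"discount_annual": 0.0})
        assert undisc.intervention.total_qalys > pair.intervention.total_qalys
        assert undisc.intervention.total_cost > pair.intervention.total_cost

    def test_cycle_count_mismatch_rejected(self):
        settings = CycleSettings(21, 20)
        costs, utils = toy_inputs()
        with pytest.raises(ValueError, match="cycles"):
            evaluate_strategy(constant_pfs_trace(10), costs, utils, settings, "A")


class TestCompareStrategies:
    def _result(self, cost, qalys, arm="A"):
        from nsclc_cea.econ_valuation import EconomicResult

        return EconomicResult(arm, cost, qalys, qalys,
                              {"all": np.array([cost])}, {"all": np.array([qalys])})

    def test_direct_division(self):
        c = compare_strategies(self._result(130_000, 3.2), self._result(100_000, 2.0),
                               wtp=35_663)
        assert c.icer == pytest.approx(25_000.0)
        assert c.cost_effective

    def test_dominance_when_cheaper_and_better(self):
        c = compare_strategies(self._result(90_000, 3.0), self._result(100_000, 2.0))
        assert c.dominance is Dominance.DOMINANT and c.cost_effective
        c2 = compare_strategies(self._result(100_000, 2.0), self._result(90_000, 3.0))
        assert c2.dominance is Dominance.DOMINATED and not c2.cost_effective

    def test_wtp_decision_rule(self):
        b = self._result(100_000, 2.0)
        below = compare_strategies(self._result(125_000, 3.0), b, wtp=35_663)
        at = compare_strategies(self._result(135_663, 3.0), b, wtp=35_663)
        assert below.cost_effective  # ICER 25,000 < 35,663
        assert not at.cost_effective  # ICER == WTP is not strictly below it

    def test_equal_effectiveness_flags_icer_undefined(self):
        c = compare_strategies(self._result(100, 2.0), self._result(90, 2.0))
        assert c.icer is None and c.dominance is Dominance.DOMINATED

    @given(dc=st.floats(-5e4, 5e4), de=st.floats(-2, 2))
    @hyp_settings(max_examples=60, deadline=None)
    def test_antisymmetry(self, dc, de):
        a = self._result(1e5 + dc, 2.0 + de, "A")
        b = self._result(1e5, 2.0, "B")
        ab = compare_strategies(a, b)
        ba = compare_strategies(b, a)
        assert ab.delta_cost == pytest.approx(-ba.delta_cost)
        assert ab.delta_qalys == pytest.approx(-ba.delta_qalys)
        flip = {Dominance.DOMINANT: Dominance.DOMINATED,
                Dominance.DOMINATED: Dominance.DOMINANT,
                Dominance.NONE: Dominance.NONE}
        assert ba.dominance is flip[ab.dominance]


def test_price_negotiation_arithmetic():
    # listing $1,657/100 mg was 40% below the reference drug; negotiated
    # $338/100 mg is then an 88% reduction relative to it
    reference = 1657.0 / (1.0 - 0.40)
    assert round(relative_price_reduction(338.0, reference)) == 88
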