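"""QALY, blindness-free-year and cost accrual."""

import dataclasses

import numpy as np
import pytest

from visioncea import markov_engine as me
from visioncea import outcomes as oc
from visioncea.model_config import (
    AdverseEventSpec,
    ConfigError,
    CostInputs,
    ModelSettings,
    UtilitySet,
    ValidationError,
)


def make_trace(rows, strategy="SoC"):
    occ = np.asarray(rows, dtype=float)
    return me.Trace(strategy, occ, 15.1 + np.arange(occ.shape[0]))


class TestDiscountFactor:
    def test_first_year_undiscounted(self):
        assert oc.discount_factor(1, 0.03) == 1.0

    def test_zero_rate_identity(self):
        assert oc.discount_factor(57, 0.0) == 1.0

    def test_third_cycle_value(self):
        assert oc.discount_factor(3, 0.03) == pytest.approx(0.942596, abs=1e-6)

    def test_invalid_cycle(self):
        with pytest.raises(ValidationError):
            oc.discount_factor(0, 0.03)


class TestAeQalyLoss:
    def test_published_adverse_events(self, config):
        assert oc.ae_qaly_loss(config.adverse_events) == pytest.approx(
            0.0124167, abs=1e-7
        )

    def test_zero_probability_zero_loss(self):
        events = [AdverseEventSpec("x", 0.5, 6.0, 0.0, 100.0)]
        assert oc.ae_qaly_loss(events) == 0.0

    def test_full_year_full_probability(self):
        events = [AdverseEventSpec("x", 0.5, 12.0, 1.0, 0.0)]
        assert oc.ae_qaly_loss(events) == pytest.approx(0.5)


class TestQalyAndYears:
    def test_additivity_in_best_state(self):
        trace = make_trace([[1, 0, 0, 0, 0, 0]] * 3)
        u = UtilitySet("EQ-5D-5L", np.array([0.71, 0.62, 0.52, 0.35, 0.15]))
        d, und = oc.qaly_total(trace, u, 0.0, ModelSettings(discount_rate=0.0))
        assert d == pytest.approx(1.42)
        assert und == pytest.approx(1.42)

    def test_death_accrues_nothing(self):
        trace = make_trace([[1, 0, 0, 0, 0, 0]] + [[0, 0, 0, 0, 0, 1]] * 2)
        u = UtilitySet("EQ-5D-5L", np.array([0.71, 0.62, 0.52, 0.35, 0.15]))
        d, und = oc.qaly_total(trace, u, 0.0, ModelSettings())
        assert (d, und) == (0.0, 0.0)

    def test_one_cycle_dot_product(self, config):
        trace = make_trace(
            [[0.23, 0.32, 0.23, 0.19, 0.03, 0]] * 2
        )
        d, _ = oc.qaly_total(trace, config.utilities, 0.0, ModelSettings())
        # 0.23*0.71 + 0.32*0.62 + 0.23*0.52 + 0.19*0.35 + 0.03*0.15
        assert d == pytest.approx(0.5523)

    def test_ae_loss_subtracted_undiscounted(self, config):
        trace = make_trace([[1, 0, 0, 0, 0, 0]] * 2)
        d, und = oc.qaly_total(trace, config.utilities, 0.01, ModelSettings())
        assert d == pytest.approx(0.71 - 0.01)
        assert und == pytest.approx(0.71 - 0.01)

    def test_blindness_free_years_exclude_worst_state(self):
        settings = ModelSettings(discount_rate=0.0)
        all_blind = make_trace([[0, 0, 0, 0, 1, 0]] * 4)
        assert oc.blindness_free_years(all_blind, settings) == (0.0, 0.0)
        one_cycle = make_trace(
            [[0.23, 0.32, 0.23, 0.19, 0.03, 0], [0.31, 0.16, 0.42, 0.11, 0, 0]]
        )
        d, _ = oc.blindness_free_years(one_cycle, settings)
        assert d == pytest.approx(1.00)

    def test_lifetime_in_best_state(self):
        settings = ModelSettings(discount_rate=0.0)
        trace = make_trace([[1, 0, 0, 0, 0, 0]] * 86)
        assert oc.blindness_free_years(trace, settings)[0] == pytest.approx(85.0)
        assert oc.life_years(trace, settings)[0] == pytest.approx(85.0)


class TestOneOffCosts:
    def test_eligibility_component_scales_by_eligible_fraction(self, config):
        comps = oc.treatment_and_testing_costs(
            "VN", config.costs, config.adverse_events
        )
        assert comps["eligibility"] == pytest.approx(271 / 0.55)
        assert round(comps["eligibility"]) == 493

    def test_treatment_bundle(self, config):
        comps = oc.treatment_and_testing_costs(
            "VN", config.costs, config.adverse_events
        )
        assert comps["treatment"] == pytest.approx(768_086.0)

    def test_expected_adverse_event_cost(self, config):
        comps = oc.treatment_and_testing_costs(
            "VN", config.costs, config.adverse_events
        )
        assert comps["adverse_events"] == pytest.approx(779.55)

    def test_zero_for_standard_of_care(self, config):
        comps = oc.treatment_and_testing_costs(
            "SoC", config.costs, config.adverse_events
        )
        assert all(v == 0.0 for v in comps.values())

    def test_zero_eligible_fraction_is_config_error(self, config):
        config.costs.eligible_fraction = 0.0
        with pytest.raises(ConfigError, match="eligible_fraction"):
            oc.treatment_and_testing_costs("VN", config.costs, [])


class TestCycleResourceCosts:
    def test_best_state_working_age_only_technical_assistance(self, config):
        out = oc.cycle_resource_costs(
            np.array([1, 0, 0, 0, 0, 0]), 30.0, config.costs, ModelSettings()
        )
        assert out["technical_assistance"] == pytest.approx(2_133.0)
        assert sum(v for k, v in out.items() if k != "technical_assistance") == 0.0

    def test_impaired_senior_components(self, config):
        out = oc.cycle_resource_costs(
            np.array([0, 0, 1, 0, 0, 0]), 70.0, config.costs, ModelSettings()
        )
        assert out["hospitalisation"] == pytest.approx(2_508.6)
        assert out["technical_assistance"] == pytest.approx(2_858.22)
        assert out["community_care"] == pytest.approx(423.78)
        assert out["residential_care"] == pytest.approx(19_361.1)
        assert sum(out.values()) == pytest.approx(25_151.7)

    def test_impaired_worker_societal_perspective(self, config):
        settings = ModelSettings(
            perspective="societal", productivity_loss_fraction=0.8
        )
        out = oc.cycle_resource_costs(
            np.array([0, 0, 1, 0, 0, 0]), 30.0, config.costs, settings
        )
        assert out["technical_assistance"] == pytest.approx(2_047.68)
        assert out["productivity"] == pytest.approx(34_274.4)
        assert out["education"] == 0.0 and out["caregiver"] == 0.0

    def test_child_education_and_senior_caregiver(self, config):
        settings = ModelSettings(perspective="societal")
        child = oc.cycle_resource_costs(
            np.array([0, 1, 0, 0, 0, 0]), 16.0, config.costs, settings
        )
        assert child["education"] == pytest.approx(21_094.0)
        senior = oc.cycle_resource_costs(
            np.array([0.5, 0.5, 0, 0, 0, 0]), 70.0, config.costs, settings
        )
        assert senior["caregiver"] == pytest.approx(
            43 * 0.25 * (144 * 0.5 + 676 * 0.5)
        )

    def test_linearity_in_unit_costs(self, config):
        occ = np.array([0.2, 0.2, 0.2, 0.2, 0.2, 0.0])
        base = oc.cycle_resource_costs(
            occ, 70.0, config.costs, ModelSettings(perspective="societal")
        )
        doubled_costs = CostInputs(
            **{
                f.name: (
                    getattr(config.costs, f.name) * 2
                    if "cost" in f.name or "annual" in f.name
                    or f.name == "vn_acquisition"
                    else getattr(config.costs, f.name)
                )
                for f in dataclasses.fields(CostInputs)
            }
        )
        doubled = oc.cycle_resource_costs(
            occ, 70.0, doubled_costs, ModelSettings(perspective="societal")
        )
        for k in base:
            assert doubled[k] == pytest.approx(2 * base[k])


class TestEvaluateStrategy:
    def test_healthcare_total_is_sum_of_components(self, config):
        trace = me.run_trace("VN", config)
        res = oc.evaluate_strategy(trace, config)
        expected = (
            res.components["treatment"]
            + res.components["eligibility"]
            + res.components["adverse_events"]
            + res.resource_use
        )
        assert res.total_healthcare_cost == pytest.approx(expected, abs=1e-6)

    def test_undiscounted_at_least_discounted(self, config):
        for strategy in ("VN", "SoC"):
            res = oc.evaluate_strategy(me.run_trace(strategy, config), config)
            assert res.qalys_undiscounted >= res.qalys
            assert res.total_cost_undiscounted >= res.total_cost
            assert res.blindness_free_years_undiscounted >= res.blindness_free_years

    def test_societal_total_nests_healthcare_total(self, config):
        trace = me.run_trace("SoC", config)
        healthcare = oc.evaluate_strategy(trace, config)
        config.settings.perspective = "societal"
        societal = oc.evaluate_strategy(me.run_trace("SoC", config), config)
        assert societal.total_cost >= healthcare.total_cost

    def test_discounted_qalys_bounded_by_discount_sum(self, config):
        res = oc.evaluate_strategy(me.run_trace("VN", config), config)
        bound = float(
            oc.discount_factors(85, config.settings.discount_rate).sum()
        ) * float(config.utilities.values.max())
        assert res.qalys <= bound

    def test_half_cycle_correction_reduces_first_year_weight(self, config):
        base = oc.evaluate_strategy(me.run_trace("VN", config), config)
        config.settings.half_cycle_correction = True
        hcc = oc.evaluate_strategy(me.run_trace("VN", config), config)
        assert hcc.qalys != base.qalys

    def test_ledger_frame_lists_all_components(self, config):
        res = oc.evaluate_strategy(me.run_trace("VN", config), config)
        df = res.ledger_frame()
        assert set(df["component"]) == set(oc.ALL_COMPONENTS)
        assert (df["undiscounted"] >= df["discounted"] - 1e-9).all()
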