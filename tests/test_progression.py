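"""Transition intensities, cycle matrices, HS5 imputation and the MLE."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from visioncea import progression as pg
from visioncea import synthetic_data as sd
from visioncea.model_config import MultistateParams, ValidationError
from visioncea.progression import FitError


class TestHazard:
    def test_exponential_is_constant(self):
        p = MultistateParams("exponential", 1.0, 0.2, {(1, 2): 0.0})
        for t in (0.0, 1.0, 37.5):
            assert pg.hazard(t, (1, 2), p) == pytest.approx(0.2)

    def test_weibull_form(self):
        # h0(t) = shape * rate * t**(shape-1) = 2 * 0.01 * 5 = 0.1
        p = MultistateParams("weibull", 2.0, 0.01, {(1, 2): 0.0})
        assert pg.hazard(5.0, (1, 2), p) == pytest.approx(0.1)

    def test_proportional_hazard_scaling(self):
        p = MultistateParams(
            "weibull", 2.0, 0.01, {(1, 2): 0.0, (2, 3): math.log(2.0)}
        )
        assert pg.hazard(5.0, (2, 3), p) == pytest.approx(0.2)

    def test_backward_transition_rejected(self):
        p = MultistateParams("weibull", 2.0, 0.01, {(1, 2): 0.0})
        with pytest.raises(ValidationError, match="forward"):
            pg.hazard(5.0, (3, 2), p)

    def test_negative_time_rejected(self):
        p = MultistateParams("weibull", 2.0, 0.01, {(1, 2): 0.0})
        with pytest.raises(ValidationError, match=">= 0"):
            pg.hazard(-1.0, (1, 2), p)

    def test_disabled_transition_has_zero_intensity(self):
        p = MultistateParams("weibull", 2.0, 0.01, {(1, 2): 0.0})
        assert pg.hazard(5.0, (1, 5), p) == 0.0

    @pytest.mark.parametrize("family", ["gompertz", "loglogistic", "lognormal"])
    def test_cumulative_hazard_integrates_hazard(self, family):
        p = MultistateParams(family, 1.4, 0.08, {(1, 2): 0.0})
        grid = np.linspace(1e-6, 12.0, 20_001)
        numeric = np.trapezoid(
            pg.baseline_hazard(grid, family, p.shape, p.rate), grid
        )
        closed = float(pg.cumulative_hazard(12.0, family, p.shape, p.rate))
        assert numeric == pytest.approx(closed, rel=1e-5)


class TestCycleTransitionMatrix:
    def test_vanishing_hazards_give_identity(self):
        p = MultistateParams("exponential", 1.0, 1e-15, {(1, 2): 0.0})
        assert np.allclose(pg.cycle_transition_matrix(0.0, p), np.eye(5), atol=1e-10)

    def test_constant_hazard_closed_form(self):
        p = MultistateParams("exponential", 1.0, 0.2, {(1, 2): 0.0})
        m = pg.cycle_transition_matrix(3.0, p)
        assert m[0, 0] == pytest.approx(math.exp(-0.2), abs=1e-10)
        assert m[0, 1] == pytest.approx(1 - math.exp(-0.2), abs=1e-10)

    def test_weibull_cycle_closed_form(self):
        # P(move in [5,6]) = 1 - exp(-rate*(6^2 - 5^2)) = 1 - e^(-0.11)
        p = MultistateParams("weibull", 2.0, 0.01, {(1, 2): 0.0})
        m = pg.cycle_transition_matrix(5.0, p)
        assert m[0, 1] == pytest.approx(1 - math.exp(-0.11), abs=1e-8)

    def test_rows_sum_to_one_and_forward_only(self):
        p = sd.plausible_longterm_params()
        m = pg.cycle_transition_matrix(10.0, p)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(m[np.tril_indices(5, k=-1)] == 0)

    def test_chapman_kolmogorov_for_constant_hazards(self):
        p = MultistateParams(
            "exponential",
            1.0,
            0.15,
            {(1, 2): 0.0, (2, 3): math.log(1.4), (3, 4): math.log(0.7),
             (1, 3): math.log(0.3), (4, 5): math.log(2.0)},
        )
        p01 = pg.cycle_transition_matrix(0.0, p)
        p12 = pg.cycle_transition_matrix(1.0, p)
        p02 = pg.cycle_transition_matrix(0.0, p, dt=2.0)
        assert np.allclose(p01 @ p12, p02, atol=1e-10)

    def test_generator_rows_sum_to_zero(self):
        p = sd.plausible_longterm_params()
        q = pg.generator_matrix(7.0, p)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        assert np.all(off >= 0)
        assert np.all(q[np.tril_indices(5, k=-1)] == 0)

    @given(bump=st.floats(0.05, 1.5))
    def test_raising_a_hazard_ratio_never_traps_mass(self, bump):
        base = sd.plausible_longterm_params()
        stay0 = pg.cycle_transition_matrix(5.0, base)[1, 1]
        raised = sd.plausible_longterm_params()
        raised.log_hr[(2, 3)] += bump
        stay1 = pg.cycle_transition_matrix(5.0, raised)[1, 1]
        assert stay1 <= stay0 + 1e-12

    def test_singular_weibull_hazard_at_origin_is_integrable(self):
        p = MultistateParams("weibull", 0.5, 0.3, {(1, 2): 0.0})
        m = pg.cycle_transition_matrix(0.0, p)
        assert np.isfinite(m).all()
        # exact: 1 - exp(-0.3 * 1**0.5)
        assert m[0, 1] == pytest.approx(1 - math.exp(-0.3), rel=1e-9)


class TestDeriveHs5Row:
    @pytest.mark.parametrize(
        "hs4_row, expected",
        [
            # published first-year rows: the HS5 row mirrors the HS4 movement
            ([0, 0, 1, 0, 0], [0, 0, 0, 1, 0]),
            ([0.50, 0, 0.25, 0.25, 0], [0, 0.50, 0, 0.25, 0.25]),
            ([0, 0, 0, 0, 1], [0, 0, 0, 0, 1]),  # clamped at the worst state
            ([0, 0, 0, 1, 0], [0, 0, 0, 0, 1]),
        ],
    )
    def test_shift_one_state_worse(self, hs4_row, expected):
        assert pg.derive_hs5_row(np.array(hs4_row, float)).tolist() == expected

    def test_invalid_row_rejected(self):
        with pytest.raises(ValidationError, match="probability row"):
            pg.derive_hs5_row(np.array([0.5, 0.2, 0, 0, 0]))

    @given(
        raw=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5).filter(
            lambda xs: sum(xs) > 1e-3
        )
    )
    def test_result_is_a_probability_row(self, raw):
        row = np.array(raw) / sum(raw)
        out = pg.derive_hs5_row(row)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out >= 0)


class TestFitMultistate:
    def test_exponential_rate_is_events_over_person_time(self):
        # 10 observed HS1->HS2 events after 1 year each + 9 subjects censored
        # at 10 years: 100 person-years, MLE rate = 10/100
        histories = [
            sd.EventHistory(k, [1, 2], [0.0, 1.0], 1.0) for k in range(10)
        ] + [sd.EventHistory(100 + k, [1], [0.0], 10.0) for k in range(9)]
        fit = pg.fit_multistate(histories, family="exponential", transitions=((1, 2),))
        assert fit.params.rate == pytest.approx(0.1, rel=1e-4)
        assert fit.n_events == 10

    def test_no_reference_events_is_an_error(self):
        histories = [sd.EventHistory(0, [2, 3], [0.0, 1.0], 2.0)]
        with pytest.raises(FitError, match="reference"):
            pg.fit_multistate(histories, family="exponential")

    def test_bias_shrinks_with_sample_size(self):
        truth = sd.plausible_longterm_params()

        def max_rel_error(n, seed):
            histories = sd.simulate_histories(truth, n, 60.0, seed)
            fit = pg.fit_multistate(histories, family="weibull")
            errs = [
                abs(fit.params.shape / truth.shape - 1),
                abs(fit.params.rate / truth.rate - 1),
            ] + [
                abs(fit.params.hazard_ratio(t) / truth.hazard_ratio(t) - 1)
                for t in truth.transitions
                if t != (1, 2)
            ]
            return max(errs)

        err_small = max_rel_error(500, seed=11)
        err_large = max_rel_error(5000, seed=11)
        assert err_large < err_small
        assert err_large < 0.2

    def test_aic_prefers_generating_family(self):
        truth = MultistateParams("weibull", 2.0, 0.01, {(1, 2): 0.0})
        histories = sd.simulate_histories(truth, 1500, 80.0, seed=5)
        fit_w = pg.fit_multistate(histories, "weibull", transitions=((1, 2),))
        fit_e = pg.fit_multistate(histories, "exponential", transitions=((1, 2),))
        assert fit_w.aic < fit_e.aic
        assert fit_w.bic < fit_e.bic

    def test_single_transition_weibull_matches_lifelines(self):
        """Independent oracle: lifelines' univariate Weibull fit on the same
        censored first-transition data."""
        lifelines = pytest.importorskip("lifelines")
        truth = MultistateParams("weibull", 1.6, 0.05, {(1, 2): 0.0})
        histories = sd.simulate_histories(truth, 2000, 40.0, seed=3)
        fit = pg.fit_multistate(histories, "weibull", transitions=((1, 2),))
        durations = [h.times[1] if len(h.times) > 1 else h.censor_time
                     for h in histories]
        observed = [1 if len(h.times) > 1 else 0 for h in histories]
        wf = lifelines.WeibullFitter().fit(durations, observed)
        # lifelines: S(t) = exp(-(t/lambda_)**rho_)  =>  rate = lambda_**-rho_
        assert fit.params.shape == pytest.approx(wf.rho_, rel=0.02)
        assert fit.params.rate == pytest.approx(wf.lambda_**-wf.rho_, rel=0.02)
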