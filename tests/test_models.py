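"""Unit and property tests for the eight choice models and the choice rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempodisc.models import (
    SV_MODELS,
    ChoiceRuleParams,
    ChoiceTrial,
    HeuristicParams,
    Option,
    SVModelParams,
    choice_log_likelihood,
    choice_probability,
    decision_value_drift,
    decision_value_itch,
    decision_value_trade,
    log_likelihood,
    standardize,
    subjective_value,
)


def _sv_params(model_id, k, s=1.0):
    return SVModelParams(model_id, k=k,
                         s=s if model_id.endswith("_scaled") else None)


def _trial(x1, t1, x2, t2, choice=1):
    return ChoiceTrial("p1", "food", 1, 1, 1,
                       immediate=Option(x1, t1), delayed=Option(x2, t2),
                       choice=choice)


class TestSubjectiveValue:
    @pytest.mark.parametrize("model_id", SV_MODELS)
    def test_zero_delay_identity(self, model_id):
        params = _sv_params(model_id, k=0.07, s=0.8)
        assert subjective_value(Option(40, 0), params) == pytest.approx(40.0)

    @pytest.mark.parametrize("model_id,k,s,expected", [
        ("hyp", 0.1, None, 20.0),                       # 40/(1+1)
        ("hyp_denom_scaled", 0.1, 2.0, 10.0),           # 40/(1+1)^2
        ("hyp_delay_scaled", 0.2, 0.5, 40.0 / (1 + 0.2 * math.sqrt(10))),
        ("exp", 0.1, None, 40.0 * math.exp(-1.0)),
    ])
    def test_closed_forms_at_delay_ten(self, model_id, k, s, expected):
        params = SVModelParams(model_id, k=k, s=s)
        assert subjective_value(Option(40, 10), params) == pytest.approx(expected, rel=1e-12)

    def test_exp_scaled_closed_form(self):
        params = SVModelParams("exp_scaled", k=0.04, s=0.5)
        # (0.04*100)^0.5 = 2 -> 40*exp(-2)
        assert subjective_value(Option(40, 100), params) == pytest.approx(
            40.0 * math.exp(-2.0), rel=1e-12)

    @pytest.mark.parametrize("model_id", SV_MODELS)
    def test_monotone_decreasing_in_delay_and_k(self, model_id):
        delays = np.linspace(0.5, 365, 40)
        for k in (0.005, 0.05, 0.5):
            sv = subjective_value(params=_sv_params(model_id, k, 0.7),
                                  amount=40.0, delay=delays)
            assert np.all(np.diff(sv) < 0)
        ks = np.linspace(0.001, 1.0, 40)
        sv_k = [subjective_value(Option(40, 90), _sv_params(model_id, k, 0.7))
                for k in ks]
        assert np.all(np.diff(sv_k) < 0)

    @pytest.mark.parametrize("model_id", SV_MODELS)
    def test_bounds(self, model_id):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = float(rng.uniform(1e-4, 2)); s = float(rng.uniform(0.1, 3))
            d = float(rng.uniform(0, 365)); a = float(rng.uniform(0.5, 40))
            sv = subjective_value(Option(a, d), _sv_params(model_id, k, s))
            assert 0.0 < sv <= a

    @pytest.mark.parametrize("scaled,unscaled", [
        ("exp_scaled", "exp"), ("hyp_delay_scaled", "hyp"), ("hyp_denom_scaled", "hyp"),
    ])
    def test_s_equal_one_reduces_to_unscaled(self, scaled, unscaled):
        ks = np.logspace(-4, 0.3, 25)
        delays = np.linspace(0.0, 365.0, 40)
        for k in ks:
            sv_s = subjective_value(params=SVModelParams(scaled, k=k, s=1.0),
                                    amount=40.0, delay=delays)
            sv_u = subjective_value(params=SVModelParams(unscaled, k=k),
                                    amount=40.0, delay=delays)
            np.testing.assert_allclose(sv_s, sv_u, rtol=0, atol=1e-12)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            SVModelParams("hyp", k=-0.1)
        with pytest.raises(ValueError):
            SVModelParams("exp_scaled", k=0.1, s=0.0)
        with pytest.raises(ValueError):
            SVModelParams("exp", k=0.1, s=2.0)  # s not a parameter of exp


class TestHeuristics:
    def test_itch_terms(self):
        t = _trial(20, 0, 40, 14)
        zero = HeuristicParams("ITCH", beta_xA=0, beta_xR=0, beta_tA=0, beta_tR=0)
        assert decision_value_itch(t, zero) == 0.0
        xa = HeuristicParams("ITCH", beta_xA=1, beta_xR=0, beta_tA=0, beta_tR=0)
        assert decision_value_itch(t, xa) == pytest.approx(20.0)
        xr = HeuristicParams("ITCH", beta_xA=0, beta_xR=1, beta_tA=0, beta_tR=0)
        assert decision_value_itch(t, xr) == pytest.approx(20.0 / 30.0)
        tr = HeuristicParams("ITCH", beta_xA=0, beta_xR=0, beta_tA=0, beta_tR=1)
        assert decision_value_itch(t, tr) == pytest.approx(14.0 / 7.0)

    def test_drift_implied_rate_term(self):
        t = _trial(20, 0, 40, 14)
        params = HeuristicParams("DRIFT", beta_xA=0, beta_xR=0, beta_tA=0, beta_xt=1)
        assert decision_value_drift(t, params) == pytest.approx(2 ** (1 / 14) - 1, rel=1e-9)

    def test_drift_zero_variance_standardization_falls_back(self):
        # identical feature values across a dataset z-score to 0, not nan
        assert np.all(standardize([3.0, 3.0, 3.0]) == 0.0)

    def test_trade_log_scaling_limits(self):
        t = _trial(20, 0, 40, 14)
        near_linear = HeuristicParams("TRADE", scaling1=1.0, scaling2=1e-9, scaling3=1.0)
        assert decision_value_trade(t, near_linear) == pytest.approx(
            20.0 - math.log(15.0), rel=1e-5)
        amount_only = HeuristicParams("TRADE", scaling1=0.0, scaling2=1.0, scaling3=1.0)
        assert decision_value_trade(t, amount_only) == pytest.approx(
            math.log(41.0) - math.log(21.0), rel=1e-9)
        same = (Option(40, 14), Option(40, 14))  # identical options
        assert decision_value_trade(same, HeuristicParams(
            "TRADE", scaling1=0.5, scaling2=1.0, scaling3=1.0)) == pytest.approx(0.0)

    def test_trade_longer_delay_penalizes(self):
        params = HeuristicParams("TRADE", scaling1=0.8, scaling2=0.5, scaling3=0.5)
        dv_short = decision_value_trade(_trial(20, 0, 40, 14), params)
        dv_long = decision_value_trade(_trial(20, 0, 40, 365), params)
        assert dv_long < dv_short

    def test_field_validation(self):
        with pytest.raises(ValueError):
            HeuristicParams("ITCH", beta_xA=1.0)  # missing weights
        with pytest.raises(ValueError):
            HeuristicParams("TRADE", scaling1=1, scaling2=1, scaling3=1, beta_xA=0.2)
        with pytest.raises(ValueError):
            HeuristicParams("TRADE", scaling1=1, scaling2=-1, scaling3=1)


class TestChoiceRule:
    def test_anchor_points(self):
        assert choice_probability(0.0) == pytest.approx(0.5)
        assert choice_probability(math.log(3.0)) == pytest.approx(0.75)
        assert choice_probability(700.0, ChoiceRuleParams(0.1)) == pytest.approx(0.9)
        assert choice_probability(-700.0, ChoiceRuleParams(0.1)) == pytest.approx(0.1)

    @given(dv=st.floats(-1e308, 1e308, allow_nan=False),
           error=st.floats(0.0, 0.2))
    @settings(max_examples=300, derandomize=True)
    def test_bounds_and_lapse_symmetry(self, dv, error):
        rule = ChoiceRuleParams(error)
        p = choice_probability(dv, rule)
        assert error <= p <= 1.0 - error
        assert p + choice_probability(-dv, rule) == pytest.approx(1.0, abs=1e-12)

    def test_error_range_validated(self):
        with pytest.raises(ValueError):
            ChoiceRuleParams(0.25)


class TestLogLikelihood:
    def test_single_trial_and_additivity(self):
        params = SVModelParams("hyp", k=0.1)
        # hand-built trial with dv = 0: SV(40, 10) = 20 = immediate amount
        t = _trial(20, 0, 40, 10, choice=1)
        ll1 = log_likelihood([t], params)
        assert ll1 == pytest.approx(math.log(0.5))
        assert log_likelihood([t] * 7, params) == pytest.approx(7 * ll1)

    def test_matches_direct_product_oracle(self):
        rng = np.random.default_rng(3)
        params = SVModelParams("exp", k=0.03)
        rule = ChoiceRuleParams(0.05)
        trials = [_trial(float(rng.uniform(2, 38)), 0, 40.0,
                         float(rng.choice([2, 14, 30, 90, 180, 365])),
                         choice=int(rng.integers(0, 2)))
                  for _ in range(8)]
        product = 1.0
        for t in trials:
            sv_d = 40.0 * math.exp(-params.k * t.delayed.delay)
            p = (1 - 2 * rule.error) * (math.exp(sv_d - t.immediate.amount)
                                        / (1 + math.exp(sv_d - t.immediate.amount))) \
                + rule.error
            product *= p if t.choice == 1 else (1 - p)
        assert log_likelihood(trials, params, rule) == pytest.approx(
            math.log(product), rel=1e-10)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], SVModelParams("hyp", k=0.1))

    def test_stable_for_extreme_decision_values(self):
        # contrary choice at a saturated probability: finite when error > 0
        rule = ChoiceRuleParams(0.02)
        ll = choice_log_likelihood(np.array([0, 1]), np.array([500.0, -500.0]), rule)
        assert np.isfinite(ll).all()
        assert ll == pytest.approx([math.log(0.02)] * 2)
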