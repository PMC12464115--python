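"""The nested RL model family: updates, weights, choice rule, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itpav.models import (MODELS, ModelParams, action_weight, choice_prob_go,
                          effective_learning_rate, enumerate_sequence_probs,
                          session_loglik, simulate_agent, update_q)
from itpav.task import generate_schedule

NESTED_PAIRS = [
    # (parent, child, neutral values that collapse the child onto the parent)
    ("M0", "M1", dict(xi=0.0)),
    ("M1", "M2", dict(b=0.0)),
    ("M2", "M3", dict(pi=0.0)),
    ("M2", "M4", dict()),   # alpha0 = alpha1 = alpha set below
    ("M3", "M5", dict()),
    ("M4", "M5", dict(pi=0.0)),
]


class TestUpdateQ:
    @pytest.mark.parametrize("q,r,alpha,expected", [
        (0.0, 1.0, 0.5, 0.5),
        (0.7, 0.7, 0.9, 0.7),   # zero prediction error leaves q unchanged
        (0.5, 0.0, 0.2, 0.4),
    ])
    def test_delta_rule(self, q, r, alpha, expected):
        assert update_q(q, r, alpha) == pytest.approx(expected)

    def test_invalid_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            update_q(0.5, 1.0, 1.5)

    @given(q=st.floats(0, 1), r=st.sampled_from([0.0, 1.0]),
           alpha=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_q_stays_in_unit_interval(self, q, r, alpha):
        assert 0.0 <= update_q(q, r, alpha) <= 1.0


class TestEffectiveLearningRate:
    @pytest.fixture
    def params(self):
        return ModelParams(alpha=0.3, tau=5, xi=0.1, b=0.1,
                           alpha0=0.6, alpha1=0.1)

    @pytest.mark.parametrize("action,timing,expected_attr", [
        ("go", "immediate", "alpha0"),
        ("nogo", "delayed", "alpha0"),
        ("go", "delayed", "alpha1"),
        ("nogo", "immediate", "alpha1"),
        ("go", "none", "alpha1"),     # no reward obtained
        ("nogo", "none", "alpha1"),
    ])
    def test_learning_bias_branches(self, params, action, timing,
                                    expected_attr):
        rate = effective_learning_rate(action, timing, params, MODELS["M4"])
        assert rate == getattr(params, expected_attr)

    def test_models_without_bias_use_single_alpha(self, params):
        for mid in ("M0", "M1", "M2", "M3"):
            rate = effective_learning_rate("go", "immediate", params,
                                           MODELS[mid])
            assert rate == params.alpha


class TestActionWeight:
    def test_nogo_weight_is_plain_q(self):
        p = ModelParams(alpha=0.2, tau=5, xi=0, b=1.0, pi=1.0)
        assert action_weight("nogo", 0.3, p, 1.0, MODELS["M3"]) == 0.3

    def test_go_weight_sums_bias_terms(self):
        p = ModelParams(alpha=0.2, tau=5, xi=0, b=0.09, pi=0.05)
        w = action_weight("go", 0.3, p, 1.0, MODELS["M3"])
        assert w == pytest.approx(0.44)

    def test_neutral_biases_reduce_to_q(self):
        p = ModelParams(alpha=0.2, tau=5, xi=0, b=0.0, pi=0.0)
        assert action_weight("go", 0.7, p, -1.0, MODELS["M3"]) == 0.7


class TestChoiceProbGo:
    def test_symmetric_weights_give_half(self):
        assert choice_prob_go(0.4, 0.4, 7.0, 0.0) == pytest.approx(0.5)

    def test_full_lapse_gives_half(self):
        assert choice_prob_go(5.0, -5.0, 10.0, 1.0) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # 0.9 * e^2 / (e^2 + 1) + 0.05
        expected = 0.9 * np.exp(2) / (np.exp(2) + 1) + 0.05
        assert choice_prob_go(1.0, 0.0, 2.0, 0.1) == pytest.approx(expected)
        assert expected == pytest.approx(0.8427, abs=1e-4)

    @given(w_go=st.floats(-5, 5), w_nogo=st.floats(-5, 5),
           tau=st.floats(0, 50), xi=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_probability_bounds_and_conservation(self, w_go, w_nogo, tau, xi):
        p = choice_prob_go(w_go, w_nogo, tau, xi)
        assert xi / 2 - 1e-12 <= p <= 1 - xi / 2 + 1e-12
        q = choice_prob_go(w_nogo, w_go, tau, xi)  # the no-go probability
        assert p + q == pytest.approx(1.0)


class TestSessionLoglik:
    def test_single_trial_symmetric_state_is_half(self, schedule3):
        sched = generate_schedule(1, 2, 0.8, seed=1)
        sched.trials = sched.trials[:1]
        p = ModelParams(alpha=0.3, tau=9.0, xi=0.0)
        df = simulate_agent(p, MODELS["M0"], sched, seed=0)
        assert session_loglik(p, MODELS["M0"], df) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("parent,child,neutral", NESTED_PAIRS)
    def test_nesting_identities(self, parent, child, neutral, schedule200,
                                rich_params):
        p_child = ModelParams(alpha=0.3, tau=4.0, xi=0.2, b=0.4, pi=0.6,
                              alpha0=0.3, alpha1=0.3)
        for name, value in neutral.items():
            setattr(p_child, name, value)
        # parent may itself lack some of the child's shared components
        p_parent = p_child.resolved(MODELS[parent])
        p_eval = p_child.resolved(MODELS[parent])
        session = simulate_agent(p_eval, MODELS[parent], schedule200, seed=3)
        ll_child = session_loglik(p_child, MODELS[child], session)
        ll_parent = session_loglik(p_parent, MODELS[parent], session)
        assert ll_child == pytest.approx(ll_parent, abs=1e-12)

    @pytest.mark.parametrize("mid", list(MODELS))
    def test_enumeration_total_probability(self, mid, schedule3, rich_params):
        probs = enumerate_sequence_probs(
            rich_params.resolved(MODELS[mid]), MODELS[mid], schedule3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(probs >= 0)

    def test_empty_session_rejected(self, schedule200, m3_params):
        import pandas as pd
        with pytest.raises(ValueError):
            session_loglik(m3_params, MODELS["M3"], pd.DataFrame(
                columns=["condition", "response", "outcome"]))


class TestSimulateAgent:
    def test_full_lapse_go_rate_half(self, schedule200):
        p = ModelParams(alpha=0.3, tau=10.0, xi=1.0)
        rates = []
        for seed in range(30):
            df = simulate_agent(p, MODELS["M1"], schedule200, seed=seed)
            rates.append((df["response"] == "go").mean())
        assert np.mean(rates) == pytest.approx(0.5, abs=0.02)

    def test_frozen_symmetric_state_go_rate_half(self, schedule200):
        p = ModelParams(alpha=0.0, tau=10.0, xi=0.0, b=0.0, pi=0.0)
        rates = []
        for seed in range(30):
            df = simulate_agent(p, MODELS["M3"], schedule200, seed=seed)
            rates.append((df["response"] == "go").mean())
        assert np.mean(rates) == pytest.approx(0.5, abs=0.02)

    def test_cue_response_bias_shifts_go_rate_by_timing(self, schedule200):
        p = ModelParams(alpha=0.2, tau=10.0, xi=0.0, b=0.0, pi=1.0)
        imm, dly = [], []
        for seed in range(60):
            df = simulate_agent(p, MODELS["M3"], schedule200, seed=seed)
            go = df["response"] == "go"
            imm.append(go[df["reward_timing"] == "immediate"].mean())
            dly.append(go[df["reward_timing"] == "delayed"].mean())
        assert np.mean(imm) > np.mean(dly) + 0.1

    def test_pavlovian_monotonicity_in_pi(self, schedule200):
        imm_rates, dly_rates = [], []
        for pi in (0.0, 0.5, 1.0):
            p = ModelParams(alpha=0.2, tau=8.0, xi=0.1, b=0.1, pi=pi)
            go_imm = go_dly = n = 0
            for seed in range(25):
                df = simulate_agent(p, MODELS["M3"], schedule200, seed=seed)
                go = df["response"] == "go"
                go_imm += go[df["reward_timing"] == "immediate"].mean()
                go_dly += go[df["reward_timing"] == "delayed"].mean()
                n += 1
            imm_rates.append(go_imm / n)
            dly_rates.append(go_dly / n)
        assert imm_rates == sorted(imm_rates)
        assert dly_rates == sorted(dly_rates, reverse=True)

    def test_identical_seed_reproduces_session(self, schedule200, m3_params):
        a = simulate_agent(m3_params, MODELS["M3"], schedule200, seed=11)
        b = simulate_agent(m3_params, MODELS["M3"], schedule200, seed=11)
        assert a.equals(b)


def test_free_parameter_counts():
    assert [MODELS[m].n_free for m in ("M0", "M1", "M2", "M3", "M4", "M5")] \
        == [2, 3, 4, 5, 5, 6]
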