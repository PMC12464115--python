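"""Hierarchical behavioural statistics: coding, calibration, BH, correlations."""

import numpy as np
import pandas as pd
import pytest

from itpav.stats import (TERMS, bh_adjust, build_design, correlate_with_mh,
                         fit_response_bias, fit_rt_bias, group_estimates,
                         moderation_scan, participant_coefficients)


def simulate_logistic_cohort(seed, n_sub=40, n_trial=200, reward=0.0,
                             reward_sd=0.3):
    """Trial table straight from the hierarchical logistic response model."""
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_sub):
        b0 = rng.normal(0.3, 0.5)
        ba = rng.normal(1.2, 0.5)
        br = rng.normal(reward, reward_sd)
        act = rng.choice(["go", "nogo"], n_trial)
        rew = rng.choice(["immediate", "delayed"], n_trial)
        blk = np.repeat([1, 2, 3, 4], n_trial // 4)
        a = np.where(act == "go", 1.0, -1.0)
        r = np.where(rew == "immediate", 1.0, -1.0)
        eta = b0 + ba * a + br * r + 0.3 * a * (blk - 2.5)
        y = rng.random(n_trial) < 1 / (1 + np.exp(-eta))
        frames.append(pd.DataFrame(dict(
            participant_id=s, required_action=act, reward_timing=rew,
            block=blk, response=np.where(y, "go", "nogo"), rt_ms=np.nan)))
    return pd.concat(frames, ignore_index=True)


class TestBuildDesign:
    def test_codes_and_centering(self, small_cohort):
        design = build_design(small_cohort.trials)
        assert set(np.unique(design["action_code"])) == {-1.0, 1.0}
        assert set(np.unique(design["reward_code"])) == {-1.0, 1.0}
        assert design["block_c"].mean() == pytest.approx(0.0)
        go_imm = small_cohort.trials.query(
            "required_action == 'go' and reward_timing == 'immediate'").index
        assert (design.loc[go_imm, "action_code"] == 1.0).all()
        assert (design.loc[go_imm, "reward_code"] == 1.0).all()

    def test_mh_column_merged_and_centered(self, small_cohort):
        mh = small_cohort.mental_health.set_index("participant_id")["depression"]
        design = build_design(small_cohort.trials, mh)
        assert "mh_c" in design
        per_sub = design.groupby("participant_id")["mh_c"].first()
        assert per_sub.mean() == pytest.approx(0.0, abs=1e-9)

    def test_factorial_term_count_doubles_with_mh(self):
        # 8 within-participant terms; each gains an mh interaction -> 16
        assert len(TERMS) == 8
        scan_terms = [t for t in TERMS] + [f"{t}:mh" for t in TERMS]
        assert len(scan_terms) == 16

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            build_design(pd.DataFrame({"participant_id": [1]}))


class TestResponseBias:
    def test_planted_reward_effect_recovered(self):
        trials = simulate_logistic_cohort(seed=1, n_sub=60, reward=0.2)
        est = fit_response_bias(build_design(trials))
        row = est[est["effect"] == "reward"].iloc[0]
        assert row["lower"] <= 0.2 <= row["upper"]
        assert abs(row["mean"] - 0.2) < 0.15
        act = est[est["effect"] == "action"].iloc[0]
        assert act["significant"] and act["mean"] > 0.5

    def test_reward_relabeling_flips_sign_exactly(self):
        trials = simulate_logistic_cohort(seed=2, n_sub=15, reward=0.3)
        flipped = trials.copy()
        flipped["reward_timing"] = np.where(
            trials["reward_timing"] == "immediate", "delayed", "immediate")
        a = fit_response_bias(build_design(trials)).set_index("effect")
        b = fit_response_bias(build_design(flipped)).set_index("effect")
        assert a.loc["reward", "mean"] == pytest.approx(
            -b.loc["reward", "mean"], abs=1e-8)
        assert a.loc["action", "mean"] == pytest.approx(
            b.loc["action", "mean"], abs=1e-8)

    def test_null_reward_effect_rarely_significant(self):
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            trials = simulate_logistic_cohort(seed=100 + i, n_sub=30)
            est = fit_response_bias(build_design(trials))
            hits += bool(est.loc[est["effect"] == "reward",
                                 "significant"].iloc[0])
        assert hits <= 4  # ~5% nominal; binomial upper bound at n=20


class TestRTBias:
    def make_rt_cohort(self, seed, interaction=0.0, n_sub=40, n_trial=200):
        rng = np.random.default_rng(seed)
        frames = []
        for s in range(n_sub):
            act = rng.choice(["go", "nogo"], n_trial)
            rew = rng.choice(["immediate", "delayed"], n_trial)
            blk = np.repeat([1, 2, 3, 4], n_trial // 4)
            a = np.where(act == "go", 1.0, -1.0)
            r = np.where(rew == "immediate", 1.0, -1.0)
            go = rng.random(n_trial) < 0.6
            mu = (np.log(230.0) + rng.normal(0, 0.05)
                  + 0.02 * a - 0.01 * r + interaction * a * r)
            rt = np.where(go, 150.0 + np.exp(rng.normal(mu, 0.2)), np.nan)
            frames.append(pd.DataFrame(dict(
                participant_id=s, required_action=act, reward_timing=rew,
                block=blk, response=np.where(go, "go", "nogo"), rt_ms=rt)))
        return pd.concat(frames, ignore_index=True)

    def test_planted_interaction_detected(self):
        trials = self.make_rt_cohort(seed=5, interaction=-0.05)
        est = fit_rt_bias(build_design(trials)).set_index("effect")
        row = est.loc["action:reward"]
        assert row["upper"] < 0

    def test_null_effects_centered_near_zero(self):
        trials = self.make_rt_cohort(seed=6)
        est = fit_rt_bias(build_design(trials)).set_index("effect")
        assert abs(est.loc["action:reward", "mean"]) < 0.02
        assert abs(est.loc["block", "mean"]) < 0.02

    def test_global_rt_shift_leaves_slopes_unchanged(self):
        trials = self.make_rt_cohort(seed=7, interaction=-0.05)
        shifted = trials.copy()
        shifted["rt_ms"] = shifted["rt_ms"] + 100.0
        a = fit_rt_bias(build_design(trials)).set_index("effect")
        b = fit_rt_bias(build_design(shifted)).set_index("effect")
        # the per-participant shift absorbs the offset; slope estimates move
        # only within Monte-Carlo error
        for term in ("action", "reward", "action:reward"):
            assert a.loc[term, "mean"] == pytest.approx(
                b.loc[term, "mean"], abs=0.01)


class TestBHAdjust:
    def test_step_up_by_hand(self):
        reject, _ = bh_adjust([0.01, 0.02, 0.04, 0.05], q=0.05)
        assert reject.all()  # largest p = 0.05 <= 0.05 * 4/4

    def test_single_p_above_q_not_rejected(self):
        reject, _ = bh_adjust([0.06], q=0.05)
        assert not reject.any()

    def test_all_tiny_p_rejected(self):
        reject, _ = bh_adjust([0.001] * 10, q=0.05)
        assert reject.all()

    def test_rejections_subset_of_unadjusted(self):
        rng = np.random.default_rng(8)
        p = rng.random(30)
        reject, _ = bh_adjust(p, q=0.05)
        assert np.all(p[reject] < 0.05)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(9)
        p = rng.random(25) ** 2
        r1, _ = bh_adjust(p, q=0.01)
        r2, _ = bh_adjust(p, q=0.10)
        assert np.all(r2[r1])  # q=0.01 rejections contained in q=0.10

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestModerationScan:
    def test_null_covariates_yield_no_discoveries(self, small_cohort):
        scan = moderation_scan(small_cohort.trials,
                               small_cohort.mental_health)
        assert len(scan["primary"]) == 17
        assert scan["primary"]["bh_significant"].sum() <= 1

    def test_single_covariate_reduces_to_unadjusted_rule(self):
        trials = simulate_logistic_cohort(seed=11, n_sub=25)
        rng = np.random.default_rng(12)
        mh = pd.DataFrame(dict(participant_id=np.arange(25),
                               score=rng.gamma(2.0, 3.0, 25)))
        scan = moderation_scan(trials, mh, q=0.05)
        primary = scan["primary"].iloc[0]
        assert bool(primary["bh_significant"]) == (
            primary["tail_p_raw"] < 0.05)

    def test_planted_moderation_recovered(self):
        # covariate scales the participant's reward sensitivity
        rng = np.random.default_rng(13)
        n_sub, n_trial = 50, 200
        mh_scores = rng.gamma(2.0, 2.0, n_sub)
        frames = []
        for s in range(n_sub):
            br = 0.1 + 0.1 * (mh_scores[s] - mh_scores.mean())
            act = rng.choice(["go", "nogo"], n_trial)
            rew = rng.choice(["immediate", "delayed"], n_trial)
            a = np.where(act == "go", 1.0, -1.0)
            r = np.where(rew == "immediate", 1.0, -1.0)
            eta = 0.2 + 1.0 * a + br * r
            y = rng.random(n_trial) < 1 / (1 + np.exp(-eta))
            frames.append(pd.DataFrame(dict(
                participant_id=s, required_action=act, reward_timing=rew,
                block=np.repeat([1, 2, 3, 4], n_trial // 4),
                response=np.where(y, "go", "nogo"), rt_ms=np.nan)))
        trials = pd.concat(frames, ignore_index=True)
        mh = pd.DataFrame(dict(participant_id=np.arange(n_sub),
                               planted=mh_scores))
        scan = moderation_scan(trials, mh)
        primary = scan["primary"].iloc[0]
        assert primary["mean"] > 0
        assert primary["bh_significant"]

    def test_zero_variance_covariate_rejected(self, small_cohort):
        mh = pd.DataFrame(dict(
            participant_id=small_cohort.mental_health["participant_id"],
            flat=1.0))
        with pytest.raises(ValueError):
            moderation_scan(small_cohort.trials, mh)


class TestCorrelateWithMH:
    def test_perfect_correlation_endpoints(self):
        idx = np.arange(30)
        x = pd.Series(np.linspace(0, 1, 30), index=idx)
        mh = pd.DataFrame(dict(participant_id=idx, same=x.to_numpy(),
                               anti=(1 - x).to_numpy()))
        out = correlate_with_mh(x, mh).set_index("covariate")
        assert out.loc["same", "r"] == pytest.approx(1.0)
        assert out.loc["anti", "r"] == pytest.approx(-1.0)

    def test_independent_draws_have_small_r(self):
        rng = np.random.default_rng(21)
        idx = np.arange(389)
        x = pd.Series(rng.standard_normal(389), index=idx)
        mh = pd.DataFrame({"participant_id": idx,
                           **{f"v{i}": rng.standard_normal(389)
                              for i in range(5)}})
        out = correlate_with_mh(x, mh)
        assert (out["r"].abs() < 0.15).all()

    def test_too_few_pairs_rejected(self):
        x = pd.Series([1.0, 2.0], index=[0, 1])
        mh = pd.DataFrame(dict(participant_id=[0, 1], v=[3.0, 4.0]))
        with pytest.raises(ValueError):
            correlate_with_mh(x, mh)


def test_group_estimates_needs_two_participants():
    with pytest.raises(ValueError):
        group_estimates(pd.DataFrame([[0.1] * 8], columns=list(TERMS)))
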