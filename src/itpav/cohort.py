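"""Synthetic study cohorts with known ground truth.

Emulates the full dataset of a titration + go/no-go study: per participant
a hyperbolic discount rate, simulated Monetary Choice Questionnaire answers
and staircase choices, a pseudorandom 200-trial task schedule, a go/no-go
session generated from that participant's true reinforcement-learning
parameters, shifted-lognormal response times for go responses, and a panel
of right-skewed mental-health covariates with a configurable correlation to
the Pavlovian cue-response bias parameter.

Default parameter locations are the cohort central tendencies typical for
this task family (alpha 0.21, tau 7.33, xi 0.17, b 0.09, pi 0.05); the
default covariate panel carries 17 symptom-style variables whose marginal
mean/SD pairs mimic common screening instruments, with zero built-in
correlation to the bias parameter (a null cohort) unless configured
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import titration as titr
from .fitting import derive_seeds
from .models import MODELS, ModelParams
from .task import generate_schedule
from .titration import DiscountAgent, impatience_score, run_titration, score_mcq, starting_amount

RESPONSE_WINDOW_MS = 600.0

#: default covariate panel: name -> (marginal mean, marginal SD)
DEFAULT_MH_PANEL: dict[str, tuple[float, float]] = {
    "total_alcohol": (3.6, 4.2), "alcohol_use": (2.4, 2.2),
    "alcohol_problems": (1.2, 2.5), "nicotine_dependence": (0.6, 1.6),
    "depression": (5.6, 5.2), "trait_anxiety": (6.0, 3.4),
    "total_adhd": (27.4, 9.9), "adhd_inattention": (14.6, 5.7),
    "adhd_hyperactivity": (12.8, 5.6), "total_eating": (7.3, 6.7),
    "eating_control": (0.9, 1.3), "eating_other": (6.4, 5.8),
    "total_impulsivity": (30.1, 10.4), "attentional_impulsivity": (8.6, 3.9),
    "motor_impulsivity": (9.7, 4.1), "nonplanning_impulsivity": (11.8, 5.0),
    "bmi": (24.2, 4.8),
}


@dataclass
class RTConfig:
    """Shifted-lognormal response-time model for go responses.

    ``rt = shift + exp(N(mu, sd))`` truncated into the response window.
    The log-scale location carries the design effects (sum-to-zero codes:
    action +1 go-required, reward +1 immediate; block centered).
    """

    shift_ms: float = 150.0
    log_mu: float = float(np.log(230.0))
    log_sd: float = 0.25
    beta_action: float = 0.01
    beta_reward: float = -0.001
    beta_action_reward: float = -0.003
    beta_block: float = -0.005
    subject_sd_mu: float = 0.10  # between-participant SD of log_mu
    subject_sd_beta: float = 0.005  # between-participant SD of each effect


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_participants: int = 389
    model_id: str = "M3"
    n_per_condition: int = 50
    max_run: int = 2
    feedback_validity: float = 0.8
    param_means: dict = field(default_factory=lambda: dict(
        alpha=0.21, tau=7.33, xi=0.17, b=0.09, pi=0.05))
    param_sds: dict = field(default_factory=lambda: dict(
        alpha=0.15, tau=3.0, xi=0.15, b=0.30, pi=0.30))
    #: cohort medians for the right-skewed parameters; alpha and xi use a
    #: lognormal hyperdistribution matched to (mean, median), mirroring the
    #: strong floor-skew of fitted learning-rate and lapse estimates
    param_medians: dict = field(default_factory=lambda: dict(
        alpha=0.13, xi=0.06))
    k_log_mean: float = float(np.log(0.008))
    k_log_sd: float = 1.0
    titration_noise: float = 1.0  # euros; 0 = deterministic choosers
    rt: RTConfig = field(default_factory=RTConfig)
    mh_panel: dict = field(default_factory=lambda: dict(DEFAULT_MH_PANEL))
    mh_corr_with_pi: float | dict = 0.0


@dataclass
class CohortData:
    """One generated cohort: observables plus stored ground truth."""

    trials: pd.DataFrame
    titration: pd.DataFrame
    params_true: pd.DataFrame
    mental_health: pd.DataFrame
    config: CohortConfig
    seed: int

    def sessions(self) -> dict:
        return {pid: g.reset_index(drop=True)
                for pid, g in self.trials.groupby("participant_id", sort=True)}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.titration.to_csv(outdir / "titration.csv", index=False)
        self.params_true.to_csv(outdir / "params_true.csv", index=False)
        self.mental_health.to_csv(outdir / "mental_health.csv", index=False)
        cfg = asdict(self.config)
        cfg["seed"] = self.seed
        pd.Series(cfg).to_json(outdir / "config.json", indent=2)

    @classmethod
    def read(cls, outdir: str | Path,
             config: CohortConfig | None = None, seed: int = 0) -> "CohortData":
        outdir = Path(outdir)
        return cls(
            trials=pd.read_csv(outdir / "trials.csv"),
            titration=pd.read_csv(outdir / "titration.csv"),
            params_true=pd.read_csv(outdir / "params_true.csv"),
            mental_health=pd.read_csv(outdir / "mental_health.csv"),
            config=config or CohortConfig(), seed=seed,
        )


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float,
                       n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean equals ``mean``.

    The underlying location is solved so that truncation does not shift the
    cohort mean away from the configured target.
    """
    if sd <= 0:
        return np.full(n, mean)
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} outside ({lo}, {hi})")

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = optimize.brentq(trunc_mean, lo - 10 * sd, hi + 10 * sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n,
                               random_state=rng)


def _skewed_lognormal(mean: float, median: float, hi: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws matched to (mean, median), clipped below ``hi``.

    mu = log(median); sigma = sqrt(2 log(mean / median)). Used for the
    floor-heavy learning-rate and lapse parameters, whose cohort medians sit
    well below their means.
    """
    if not 0 < median <= mean:
        raise ValueError("need 0 < median <= mean for a right-skewed draw")
    sigma = np.sqrt(2.0 * np.log(mean / median))
    if sigma == 0:
        return np.full(n, mean)

    def trunc_mean(mu):  # mean of the below-``hi`` lognormal after redraws
        z = (np.log(hi) - mu) / sigma
        return (np.exp(mu + sigma ** 2 / 2.0)
                * stats.norm.cdf(z - sigma) / stats.norm.cdf(z)) - mean

    mu = optimize.brentq(trunc_mean, np.log(median) - 2.0,
                         np.log(hi) + 1.0)
    draws = rng.lognormal(mu, sigma, size=n)
    while True:  # redraw the small clipped tail to stay inside the box
        over = draws >= hi
        if not over.any():
            return draws
        draws[over] = rng.lognormal(mu, sigma, size=int(over.sum()))


def sample_params(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw per-participant true RL parameters within their boxes.

    Parameters with a configured cohort median (alpha, xi by default) are
    drawn from mean/median-matched lognormals; the rest use truncated
    normals whose truncated mean equals the configured location.
    """
    from .models import BOUNDS

    rng = np.random.default_rng(seed)
    n = config.n_participants
    cols = {}
    for name in ("alpha", "tau", "xi", "b", "pi"):
        lo, hi = BOUNDS[name]
        if name in config.param_medians and config.param_sds[name] > 0:
            cols[name] = _skewed_lognormal(
                config.param_means[name], config.param_medians[name],
                hi, n, rng)
        else:
            cols[name] = _matched_truncnorm(
                config.param_means[name], config.param_sds[name],
                lo, hi, n, rng)
    if MODELS[config.model_id].has_learning_bias:
        for name in ("alpha0", "alpha1"):
            m = config.param_means.get(name, config.param_means["alpha"])
            s = config.param_sds.get(name, config.param_sds["alpha"])
            cols[name] = _matched_truncnorm(m, s, 0.0, 1.0, n, rng)
    df = pd.DataFrame(cols)
    df.insert(0, "participant_id", np.arange(n))
    return df


def sample_mh(config: CohortConfig, true_pi: np.ndarray,
              seed: int) -> pd.DataFrame:
    """Generate the covariate panel via a Gaussian copula on the bias scores.

    Each covariate gets a right-skewed (gamma) marginal with the configured
    mean/SD and correlates with the true cue-response bias at the configured
    level (0 yields a null cohort).
    """
    rng = np.random.default_rng(seed)
    n = len(true_pi)
    z_pi = (true_pi - np.mean(true_pi)) / (np.std(true_pi) or 1.0)
    cols = {"participant_id": np.arange(n)}
    for name, (mean, sd) in config.mh_panel.items():
        if sd <= 0 or mean <= 0:
            raise ValueError(f"covariate {name!r}: mean and sd must be > 0")
        rho = (config.mh_corr_with_pi.get(name, 0.0)
               if isinstance(config.mh_corr_with_pi, dict)
               else config.mh_corr_with_pi)
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation for {name!r} outside [-1, 1]")
        z = rho * z_pi + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
        cols[name] = stats.gamma.ppf(u, shape, scale=scale)
    return pd.DataFrame(cols)


def sample_rt(condition: str, correct: bool, rt: RTConfig,
              rng: np.random.Generator, block_c: float = 0.0,
              mu_offset: float = 0.0) -> float:
    """One go-response RT in (0, 600] ms from the shifted lognormal."""
    from .task import condition_components

    action, timing = condition_components(condition)
    a = 1.0 if action == "go" else -1.0
    r = 1.0 if timing == "immediate" else -1.0
    mu = (rt.log_mu + mu_offset + rt.beta_action * a + rt.beta_reward * r
          + rt.beta_action_reward * a * r + rt.beta_block * block_c)
    for _ in range(200):  # truncate into the response window
        value = rt.shift_ms + np.exp(rng.normal(mu, rt.log_sd))
        if value <= RESPONSE_WINDOW_MS:
            return float(value)
    return RESPONSE_WINDOW_MS


def _attach_rts(session: pd.DataFrame, rt: RTConfig,
                subject_mu: float, subject_betas: np.ndarray,
                rng: np.random.Generator) -> None:
    """Vectorised shifted-lognormal RTs for the session's go responses."""
    go = (session["response"] == "go").to_numpy()
    a = np.where(session["required_action"] == "go", 1.0, -1.0)
    r = np.where(session["reward_timing"] == "immediate", 1.0, -1.0)
    blk = session["block"].to_numpy(float) - 2.5
    mu = (rt.log_mu + subject_mu
          + (rt.beta_action + subject_betas[0]) * a
          + (rt.beta_reward + subject_betas[1]) * r
          + (rt.beta_action_reward + subject_betas[2]) * a * r
          + (rt.beta_block + subject_betas[3]) * blk)
    n = len(session)
    values = rt.shift_ms + np.exp(rng.normal(mu, rt.log_sd, size=n))
    for _ in range(200):
        over = values > RESPONSE_WINDOW_MS
        if not over.any():
            break
        values[over] = rt.shift_ms + np.exp(
            rng.normal(mu[over], rt.log_sd, size=int(over.sum())))
    values = np.minimum(values, RESPONSE_WINDOW_MS)
    session["rt_ms"] = np.where(go, values, np.nan)


def generate_cohort(config: CohortConfig, seed: int = 0) -> CohortData:
    """Generate a complete synthetic cohort, reproducible from ``seed``."""
    from .models import simulate_agent

    spec = MODELS[config.model_id]
    n = config.n_participants
    seeds = derive_seeds(seed, 4 + 2 * n)
    params = sample_params(config, int(seeds[0]))
    mh = sample_mh(config, params["pi"].to_numpy(), int(seeds[1]))
    rng = np.random.default_rng(int(seeds[2]))

    sessions, titr_rows = [], []
    for i in range(n):
        k_true = float(np.exp(rng.normal(config.k_log_mean, config.k_log_sd)))
        agent = DiscountAgent(k_true, config.titration_noise)
        choices = agent.mcq_choices(rng=rng if config.titration_noise > 0 else None)
        k_hat = score_mcq(choices)
        start = starting_amount(k_hat)
        result = run_titration(
            agent.staircase_chooser(rng if config.titration_noise > 0 else None),
            start)
        titr_rows.append(dict(
            participant_id=i, k_true=k_true, k_scored=k_hat, start=start,
            matched_amount=result.matched_amount, n_trials=result.n_trials,
            converged=result.converged, excluded_reason=result.excluded_reason,
            impatience=(impatience_score(result.matched_amount)
                        if result.converged and result.matched_amount >= 1
                        else np.nan),
        ))

        schedule = generate_schedule(
            config.n_per_condition, config.max_run,
            config.feedback_validity, seed=int(seeds[4 + 2 * i]))
        true_p = ModelParams(
            alpha=float(params["alpha"].iat[i]), tau=float(params["tau"].iat[i]),
            xi=float(params["xi"].iat[i]), b=float(params["b"].iat[i]),
            pi=float(params["pi"].iat[i]),
            alpha0=(float(params["alpha0"].iat[i]) if "alpha0" in params else None),
            alpha1=(float(params["alpha1"].iat[i]) if "alpha1" in params else None),
        ).resolved(spec)
        session = simulate_agent(true_p, spec, schedule,
                                 seed=int(seeds[5 + 2 * i]), participant_id=i)
        subject_mu = rng.normal(0.0, config.rt.subject_sd_mu)
        subject_betas = rng.normal(0.0, config.rt.subject_sd_beta, size=4)
        _attach_rts(session, config.rt, subject_mu, subject_betas, rng)
        sessions.append(session)

    return CohortData(
        trials=pd.concat(sessions, ignore_index=True),
        titration=pd.DataFrame(titr_rows),
        params_true=params,
        mental_health=mh,
        config=config,
        seed=seed,
    )
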