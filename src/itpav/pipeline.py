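"""End-to-end pipeline: simulate -> titrate -> fit -> validate -> stats,
plus the simulation-based power scan for the Pavlovian reward effect.

Stages communicate only through files written into the run directory
(CSV/JSON), so any stage can be re-run or inspected in isolation. Every
stochastic stage draws its seed deterministically from the run's master
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as bstats
from .cohort import CohortConfig, CohortData, generate_cohort
from .fitting import aic_table, derive_seeds, fit_cohort, model_frequency
from .models import MODELS, ModelParams
from .task import generate_schedule
from .validation import model_recovery, parameter_recovery, posterior_predictive

ALL_STAGES = ("simulate", "fit", "validate", "stats", "power")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple = tuple(MODELS)
    winning_model: str = "M3"
    recovery_agents: int = 30
    recovery_per_model: int = 6
    ppc_sims: int = 10
    ppc_participants: int = 20
    fdr_q: float = 0.05
    power_effect: float = 0.17
    power_n_grid: tuple = (30, 60, 120)
    power_replicates: int = 20


def power_scan(
    effect: float,
    n_grid,
    replicates: int,
    seed: int = 0,
    n_trials: int = 200,
    alpha: float = 0.05,
    reward_slope_sd: float = 0.3,
) -> pd.DataFrame:
    """Simulation-based power for the Pavlovian reward effect.

    For each sample size, cohorts are simulated directly from the
    hierarchical logistic response model with the planted reward effect
    (log-odds, sum-to-zero scale) and population effects typical of the
    task (general go tendency, strong action effect, block-by-action
    learning trend); the reduced response-bias test is the two-stage
    population test of the reward coefficient. Returns power per n.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seeds = derive_seeds(seed, len(list(n_grid)) * replicates)
    rows = []
    j = 0
    per_block = max(n_trials // 4, 1)
    for n in n_grid:
        hits = 0
        for _rep in range(replicates):
            rng = np.random.default_rng(int(seeds[j])); j += 1
            frames = []
            for s in range(n):
                b0 = rng.normal(0.32, 0.5)
                ba = rng.normal(1.3, 0.6)
                br = rng.normal(effect, reward_slope_sd)
                bab = rng.normal(0.52, 0.2)  # action x block learning trend
                act = rng.choice([1.0, -1.0], n_trials)
                rew = rng.choice([1.0, -1.0], n_trials)
                blk = np.repeat(np.arange(4) - 1.5,
                                per_block)[:n_trials]
                eta = b0 + ba * act + br * rew + bab * act * blk
                y = (rng.random(n_trials)
                     < 1.0 / (1.0 + np.exp(-eta))).astype(float)
                frames.append(pd.DataFrame(dict(
                    participant_id=s, response=y, action_code=act,
                    reward_code=rew, block_c=blk,
                    rt_ms=np.nan)))
            design = pd.concat(frames, ignore_index=True)
            est = bstats.group_estimates(
                bstats.participant_coefficients(design, "response"),
                level=1.0 - alpha)
            row = est[est["effect"] == "reward"].iloc[0]
            hits += bool(row["significant"])
        rows.append(dict(n=int(n), effect=effect,
                         power=hits / replicates, replicates=replicates))
    return pd.DataFrame(rows)


def _model_comparison(fits: pd.DataFrame) -> dict:
    table = aic_table(fits)
    freq = model_frequency(table)
    return dict(
        median_aic={m: float(table[m].median()) for m in table.columns},
        model_frequency={m: float(freq[m]) for m in freq.index},
        n_participants=int(len(table)),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the summary report (also written to ``summary.json``); every
    stage's artifacts land in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = dict(zip(ALL_STAGES, derive_seeds(config.seed, len(ALL_STAGES))))
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    cohort: CohortData | None = None
    if "simulate" in config.stages:
        cohort = generate_cohort(config.cohort, seed=int(stage_seeds["simulate"]))
        cohort.write(outdir / "cohort")
        summary["simulate"] = dict(
            n_participants=config.cohort.n_participants,
            n_trials=int(len(cohort.trials)),
            titration_converged=int(cohort.titration["converged"].sum()),
        )
    elif {"fit", "stats"} & set(config.stages):
        cohort = CohortData.read(outdir / "cohort", config.cohort, config.seed)

    fits = None
    if "fit" in config.stages:
        specs = [MODELS[m] for m in config.models]
        fits = fit_cohort(cohort.sessions(), specs,
                          seed=int(stage_seeds["fit"]))
        fits.to_csv(outdir / "fits.csv", index=False)
        comparison = _model_comparison(fits)
        (outdir / "model_comparison.json").write_text(
            json.dumps(comparison, indent=2))
        summary["fit"] = comparison

    if "validate" in config.stages:
        spec = MODELS[config.winning_model]
        schedule = generate_schedule(
            config.cohort.n_per_condition, config.cohort.max_run,
            config.cohort.feedback_validity, seed=int(stage_seeds["validate"]))
        recovery = parameter_recovery(
            spec, config.recovery_agents, schedule,
            seed=int(stage_seeds["validate"]))
        confusion = model_recovery(
            [MODELS[m] for m in config.models], config.recovery_per_model,
            schedule, seed=int(stage_seeds["validate"]) + 1)
        report = dict(
            parameter_recovery=dict(
                model=spec.id, correlation=recovery.correlation,
                bias=recovery.bias, rmse=recovery.rmse),
            model_recovery=confusion.round(4).to_dict(),
        )
        if fits is not None and cohort is not None:
            sessions = cohort.sessions()
            ids = list(sessions)[: config.ppc_participants]
            win = fits[fits["model"] == config.winning_model]
            win = win.set_index("participant_id")
            pairs, obs = [], []
            for pid in ids:
                row = win.loc[pid]
                pairs.append((ModelParams(
                    alpha=row["alpha"], tau=row["tau"], xi=row["xi"],
                    b=row["b"], pi=row["pi"], alpha0=row["alpha0"],
                    alpha1=row["alpha1"]).resolved(spec), spec))
                obs.append(sessions[pid])
            ppc = posterior_predictive(
                pairs, obs, schedule, n_sims=config.ppc_sims,
                seed=int(stage_seeds["validate"]) + 2)
            report["posterior_predictive"] = dict(
                coverage=ppc.coverage,
                discrepancy=ppc.discrepancy.round(4).to_dict())
        (outdir / "validation.json").write_text(json.dumps(report, indent=2))
        summary["validate"] = report

    if "stats" in config.stages:
        design = bstats.build_design(cohort.trials)
        response = bstats.fit_response_bias(design)
        response.to_csv(outdir / "response_bias.csv", index=False)
        rt = bstats.fit_rt_bias(design)
        rt.to_csv(outdir / "rt_bias.csv", index=False)
        moderation = bstats.moderation_scan(
            cohort.trials, cohort.mental_health, "response", config.fdr_q)
        moderation["primary"].to_csv(outdir / "moderation_primary.csv",
                                     index=False)
        moderation["effects"].to_csv(outdir / "moderation_effects.csv",
                                     index=False)
        corr_rows = {}
        impatience = cohort.titration.set_index("participant_id")["impatience"]
        corr_imp = bstats.correlate_with_mh(impatience, cohort.mental_health,
                                            config.fdr_q)
        corr_imp.to_csv(outdir / "impatience_correlations.csv", index=False)
        corr_rows["impatience_bh_discoveries"] = int(
            corr_imp["bh_significant"].sum())
        if fits is not None:
            win = fits[fits["model"] == config.winning_model]
            pi_hat = win.set_index("participant_id")["pi"]
            corr_pi = bstats.correlate_with_mh(pi_hat, cohort.mental_health,
                                               config.fdr_q)
            corr_pi.to_csv(outdir / "pi_correlations.csv", index=False)
            corr_rows["pi_bh_discoveries"] = int(
                corr_pi["bh_significant"].sum())
        reward = response[response["effect"] == "reward"].iloc[0]
        summary["stats"] = dict(
            reward_effect=float(reward["mean"]),
            reward_hdi=[float(reward["lower"]), float(reward["upper"])],
            reward_significant=bool(reward["significant"]),
            overall_go_rate=float(design["response"].mean()),
            moderation_bh_discoveries=int(
                moderation["primary"]["bh_significant"].sum()),
            **corr_rows,
        )

    if "power" in config.stages:
        power = power_scan(config.power_effect, config.power_n_grid,
                           config.power_replicates,
                           seed=int(stage_seeds["power"]))
        power.to_csv(outdir / "power.csv", index=False)
        summary["power"] = power.to_dict(orient="records")

    summary_cfg = asdict(config)
    summary["config"] = json.loads(json.dumps(summary_cfg, default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    default=float))
    return summary
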