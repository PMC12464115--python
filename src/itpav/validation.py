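"""Model validation battery: parameter recovery, model recovery, posterior
predictive checks.

Parameter recovery simulates agents at known parameters, refits the same
model, and reports true-vs-recovered Pearson correlations, bias and RMSE.
Model recovery simulates from every model, fits all candidates, assigns the
winner by lowest AIC, and tabulates the row-normalised confusion matrix.
Posterior predictive checks re-simulate sessions at fitted (or true)
parameters and compare condition-wise go-rate trajectories against the
observed data with a Monte-Carlo band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import PriorSpec, derive_seeds, fit_map
from .models import MODELS, ModelParams, ModelSpec, simulate_agent
from .task import CONDITIONS, TaskSchedule

#: default generative ranges: uniform draws over slightly shrunken boxes to
#: avoid boundary pile-up (configurable per call)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.05, 0.6), "alpha0": (0.05, 0.6), "alpha1": (0.05, 0.6),
    "tau": (1.0, 15.0), "xi": (0.0, 0.4), "b": (-1.0, 1.0),
    "pi": (-1.0, 1.0),
}


@dataclass
class RecoveryReport:
    """True-vs-recovered summary for one model."""

    model_id: str
    n_agents: int
    seed: int
    correlation: dict = field(default_factory=dict)  # name -> r (NaN if undefined)
    bias: dict = field(default_factory=dict)  # mean(recovered - true)
    rmse: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None  # long true/recovered values


def _draw_params(spec: ModelSpec, ranges: dict, n: int,
                 rng: np.random.Generator) -> list[ModelParams]:
    from .models import BOUNDS

    draws = []
    for _ in range(n):
        values = {}
        for name in spec.param_names:
            lo, hi = ranges.get(name, DEFAULT_RANGES[name])
            blo, bhi = BOUNDS[name]
            if not (blo <= lo <= hi <= bhi):
                raise ValueError(f"range for {name!r} outside its box")
            values[name] = float(rng.uniform(lo, hi))
        draws.append(ModelParams(**values).resolved(spec))
    return draws


def parameter_recovery(
    spec: ModelSpec,
    n_agents: int,
    schedule: TaskSchedule,
    seed: int = 0,
    ranges: dict | None = None,
    priors: PriorSpec = PriorSpec(),
    truths: list[ModelParams] | None = None,
) -> RecoveryReport:
    """Simulate-at-known-truth, refit, and correlate true with recovered.

    Truths are uniform draws over ``ranges`` by default; pass ``truths``
    (e.g. draws from the synthetic-cohort hyperdistribution) to assess
    recovery under a specific population of agents.
    """
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    rng = np.random.default_rng(seed)
    if truths is None:
        ranges = dict(DEFAULT_RANGES, **(ranges or {}))
        truths = _draw_params(spec, ranges, n_agents, rng)
    elif len(truths) != n_agents:
        raise ValueError("len(truths) must equal n_agents")
    seeds = derive_seeds(seed, 2 * n_agents)
    rows = []
    for i, true_p in enumerate(truths):
        session = simulate_agent(true_p, spec, schedule, seed=int(seeds[2 * i]))
        fit = fit_map(session, spec, priors, seed=int(seeds[2 * i + 1]))
        for name in spec.param_names:
            rows.append(dict(agent=i, parameter=name,
                             true=getattr(true_p, name),
                             recovered=getattr(fit.params, name)))
    table = pd.DataFrame(rows)
    report = RecoveryReport(spec.id, n_agents, seed, table=table)
    for name, g in table.groupby("parameter"):
        true, rec = g["true"].to_numpy(), g["recovered"].to_numpy()
        if np.std(true) == 0:
            r = np.nan  # undefined under zero-variance truths
        else:
            r = float(stats.pearsonr(true, rec)[0])
        report.correlation[name] = r
        report.bias[name] = float(np.mean(rec - true))
        report.rmse[name] = float(np.sqrt(np.mean((rec - true) ** 2)))
    return report


def model_recovery(
    specs: list[ModelSpec] | None = None,
    n_agents_per_model: int = 10,
    schedule: TaskSchedule | None = None,
    seed: int = 0,
    ranges: dict | None = None,
    priors: PriorSpec = PriorSpec(),
) -> pd.DataFrame:
    """Confusion matrix of AIC winners (rows: generating model, normalised).

    Ties for the lowest AIC split the agent's weight equally among the tied
    models, so every row remains a probability vector.
    """
    if specs is None:
        specs = list(MODELS.values())
    if schedule is None:
        raise ValueError("a schedule is required")
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    ids = [s.id for s in specs]
    confusion = pd.DataFrame(0.0, index=ids, columns=ids)
    seeds = derive_seeds(
        seed, len(specs) * (1 + n_agents_per_model * (1 + len(specs))))
    j = 0
    for gen_spec in specs:
        rng = np.random.default_rng(int(seeds[j])); j += 1
        truths = _draw_params(gen_spec, ranges, n_agents_per_model, rng)
        for i, true_p in enumerate(truths):
            session = simulate_agent(true_p, gen_spec, schedule,
                                     seed=int(seeds[j])); j += 1
            aics = {}
            for fit_spec in specs:
                aics[fit_spec.id] = fit_map(
                    session, fit_spec, priors, seed=int(seeds[j])).aic
                j += 1
            values = np.array(list(aics.values()))
            winners = [m for m, a in aics.items()
                       if np.isclose(a, values.min())]
            for w in winners:
                confusion.loc[gen_spec.id, w] += 1.0 / len(winners)
    return confusion.div(confusion.sum(axis=1), axis=0)


@dataclass
class PPCReport:
    """Observed vs simulated go-rate trajectories per condition."""

    observed: pd.DataFrame  # condition x presentation -> observed go rate
    simulated_mean: pd.DataFrame
    simulated_lo: pd.DataFrame
    simulated_hi: pd.DataFrame
    coverage: float  # fraction of (condition, presentation) bins in band
    discrepancy: pd.Series  # per-condition mean |observed - simulated|
    mean_mc_se: float  # Monte-Carlo s.e. of the simulated mean trajectory
    n_sims: int


def _condition_trajectory(sessions: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean go rate by condition and within-condition presentation number."""
    stacked = pd.concat(sessions, ignore_index=True)
    stacked = stacked.sort_values(["participant_id", "trial"])
    stacked["presentation"] = stacked.groupby(
        ["participant_id", "condition"]).cumcount() + 1
    stacked["go"] = (stacked["response"] == "go").astype(float)
    return (stacked.pivot_table(index="condition", columns="presentation",
                                values="go", aggfunc="mean")
            .reindex(list(CONDITIONS)))


def posterior_predictive(
    fits: list[tuple[ModelParams, ModelSpec]],
    sessions: list[pd.DataFrame],
    schedule: TaskSchedule,
    n_sims: int = 20,
    seed: int = 0,
    band: float = 0.95,
) -> PPCReport:
    """Simulate ``n_sims`` replicate cohorts at the fitted parameters and
    compare go-rate learning curves against the observed sessions."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if len(fits) != len(sessions):
        raise ValueError("one (params, spec) pair per observed session")
    observed = _condition_trajectory(sessions)
    seeds = derive_seeds(seed, n_sims * len(fits))
    replicates = []
    j = 0
    for _s in range(n_sims):
        sims = []
        for i, (params, spec) in enumerate(fits):
            sims.append(simulate_agent(params, spec, schedule,
                                       seed=int(seeds[j]), participant_id=i))
            j += 1
        replicates.append(_condition_trajectory(sims).to_numpy())
    cube = np.stack(replicates)  # (n_sims, condition, presentation)
    alpha = (1.0 - band) / 2.0
    sim_mean = pd.DataFrame(cube.mean(axis=0), index=observed.index,
                            columns=observed.columns)
    sim_lo = pd.DataFrame(np.quantile(cube, alpha, axis=0),
                          index=observed.index, columns=observed.columns)
    sim_hi = pd.DataFrame(np.quantile(cube, 1 - alpha, axis=0),
                          index=observed.index, columns=observed.columns)
    obs = observed.to_numpy()
    inside = (obs >= sim_lo.to_numpy()) & (obs <= sim_hi.to_numpy())
    coverage = float(np.mean(inside))
    discrepancy = pd.Series(
        np.abs(obs - sim_mean.to_numpy()).mean(axis=1), index=observed.index)
    mean_mc_se = float(np.nanmean(cube.std(axis=0, ddof=1) / np.sqrt(n_sims))
                       if n_sims > 1 else np.nan)
    return PPCReport(observed, sim_mean, sim_lo, sim_hi, coverage,
                     discrepancy, mean_mc_se, n_sims)
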