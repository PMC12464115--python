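"""Hierarchical behavioural statistics for the go/no-go task.

Response bias and RT bias are estimated with a two-stage hierarchical
(summary-statistics) approach:

* Stage 1 fits every participant's own regression over the full factorial
  design -- required action x reward timing x centered block, sum-to-zero
  coded -- a ridge-penalised logistic regression for the binary go response
  (the penalty acts as a weakly informative Gaussian prior and guards
  against separation in near-deterministic responders), and an ordinary
  least-squares regression of log(rt - shift) for go-response RTs (the
  shifted-lognormal model on the log scale; the shift is fixed per
  participant below their fastest response).
* Stage 2 treats the per-participant coefficients as draws from a Gaussian
  population and reports, for every fixed effect, the posterior mean and
  95% highest-density interval of the population mean under a flat prior
  (a Student-t posterior), plus the two-sided posterior tail probability.
  Because every participant contributes every coefficient, the random-effect
  structure is maximal by construction.

Mental-health moderation regresses the stage-1 coefficients on the
mean-centered covariate (one model per covariate); the coefficient-on-
covariate slope is the cross-level interaction. Benjamini-Hochberg
correction is applied across covariates to the two-sided tail
probabilities of the primary reward x covariate term, and intervals are
re-reported at the BH-adjusted credible level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

#: fixed-effect terms of the full factorial design, in design-matrix order
TERMS = ("Intercept", "action", "reward", "action:reward",
         "block", "action:block", "reward:block", "action:reward:block")

RT_SHIFT_MAX_FRACTION = 0.95  # shift is clamped below the fastest go RT


def estimate_rt_shift(rt: np.ndarray) -> float:
    """Per-participant shift of the shifted-lognormal RT distribution.

    Three-quantile (q10, q50, q90) closed-form estimator: for a shifted
    lognormal the log-scale distribution is symmetric, so
    (q50 - s)^2 = (q10 - s)(q90 - s), giving
    s = (q10 q90 - q50^2) / (q10 + q90 - 2 q50). Being a function of
    quantiles it is exactly equivariant under global RT shifts. The result
    is clamped to [0, 0.95 x fastest RT] to keep log(rt - s) defined.
    """
    q10, q50, q90 = np.quantile(rt, [0.1, 0.5, 0.9])
    denom = q10 + q90 - 2.0 * q50
    s = (q10 * q90 - q50 ** 2) / denom if abs(denom) > 1e-9 else 0.0
    return float(np.clip(s, 0.0, RT_SHIFT_MAX_FRACTION * rt.min()))


def build_design(trials: pd.DataFrame,
                 mh_score: pd.Series | None = None) -> pd.DataFrame:
    """Sum-to-zero coded trial-level design table.

    Codes: action +1 for go-required / -1 for no-go-required trials, reward
    +1 immediate / -1 delayed, block centered (-1.5 ... +1.5 for four
    blocks). ``mh_score`` (indexed by participant id) is mean-centered and
    merged as ``mh_c`` when supplied.
    """
    required = {"participant_id", "required_action", "reward_timing",
                "block", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    bad = set(trials["required_action"].unique()) - {"go", "nogo"}
    bad |= set(trials["reward_timing"].unique()) - {"immediate", "delayed"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    design = pd.DataFrame({
        "participant_id": trials["participant_id"].to_numpy(),
        "response": (trials["response"] == "go").astype(float).to_numpy(),
        "rt_ms": trials["rt_ms"].to_numpy() if "rt_ms" in trials else np.nan,
        "action_code": np.where(trials["required_action"] == "go", 1.0, -1.0),
        "reward_code": np.where(trials["reward_timing"] == "immediate",
                                1.0, -1.0),
        "block_c": trials["block"].to_numpy(float)
        - trials["block"].to_numpy(float).mean(),
    })
    if mh_score is not None:
        centred = mh_score - mh_score.mean()
        design["mh_c"] = design["participant_id"].map(centred).to_numpy()
    return design


def _design_matrix(d: pd.DataFrame) -> np.ndarray:
    a, r, blk = (d["action_code"].to_numpy(), d["reward_code"].to_numpy(),
                 d["block_c"].to_numpy())
    return np.column_stack([np.ones(len(d)), a, r, a * r,
                            blk, a * blk, r * blk, a * r * blk])


def _penalized_logistic(X: np.ndarray, y: np.ndarray,
                        penalty: float = 1.0) -> np.ndarray:
    """Ridge-penalised logistic regression (intercept unpenalised)."""

    def nll(beta):
        eta = X @ beta
        return (np.sum(np.logaddexp(0.0, eta) - y * eta)
                + 0.5 * penalty * np.sum(beta[1:] ** 2))

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        g = X.T @ (p - y)
        g[1:] += penalty * beta[1:]
        return g

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad,
                            method="BFGS", options=dict(maxiter=500))
    return res.x


def participant_coefficients(
    design: pd.DataFrame, dv: str = "response", penalty: float = 1.0,
) -> pd.DataFrame:
    """Stage 1: one full-factorial regression per participant.

    ``dv='response'`` fits penalised logistic regressions on the go
    indicator over all trials. ``dv='rt'`` fits OLS on log(rt - shift) over
    go responses only; participants with fewer than twice as many usable go
    responses as design terms are dropped (too few trials to identify their
    coefficients).
    """
    if len(design) == 0:
        raise ValueError("empty design")
    rows = {}
    for pid, g in design.groupby("participant_id", sort=True):
        if dv == "response":
            X = _design_matrix(g)
            rows[pid] = _penalized_logistic(X, g["response"].to_numpy(),
                                            penalty)
        elif dv == "rt":
            g = g[(g["response"] == 1.0) & np.isfinite(g["rt_ms"])]
            if len(g) < 2 * len(TERMS):
                continue
            rt = g["rt_ms"].to_numpy()
            y = np.log(rt - estimate_rt_shift(rt))
            X = _design_matrix(g)
            rows[pid], *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            raise ValueError("dv must be 'response' or 'rt'")
    if not rows:
        raise ValueError("no participant had enough usable trials")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TERMS))


def group_estimates(coefs: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Stage 2: flat-prior Gaussian population summary per coefficient.

    Returns one row per effect: posterior mean, HDI bounds at ``level``
    (Student-t, symmetric, so highest-density and equal-tailed coincide),
    two-sided posterior tail probability, and a significance flag (interval
    excludes 0).
    """
    n = len(coefs)
    if n < 2:
        raise ValueError("need at least 2 participants")
    out = []
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    for term in coefs.columns:
        x = coefs[term].to_numpy()
        mean = float(np.mean(x))
        se = float(np.std(x, ddof=1) / np.sqrt(n))
        lower, upper = mean - tcrit * se, mean + tcrit * se
        tail = 2.0 * float(stats.t.sf(abs(mean) / se, n - 1)) if se > 0 else 0.0
        out.append(dict(effect=term, mean=mean, se=se, lower=lower,
                        upper=upper, tail_p=tail,
                        significant=bool(lower > 0 or upper < 0), n=n))
    return pd.DataFrame(out)


def fit_response_bias(design: pd.DataFrame, level: float = 0.95,
                      penalty: float = 1.0) -> pd.DataFrame:
    """Hierarchical logistic response-bias estimates (log-odds scale)."""
    coefs = participant_coefficients(design, "response", penalty)
    return group_estimates(coefs, level)


def fit_rt_bias(design: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Hierarchical shifted-lognormal RT-bias estimates (log-ms scale)."""
    coefs = participant_coefficients(design, "rt")
    return group_estimates(coefs, level)


def back_transform_rt(log_ms: float, shift_ms: float) -> float:
    """Marginal mean on the response scale (ms) from a log-scale location."""
    return shift_ms + float(np.exp(log_ms))


def bh_adjust(p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _second_level(coefs: pd.DataFrame, covariate: pd.Series,
                  level: float = 0.95) -> pd.DataFrame:
    """Regress stage-1 coefficients on a centered covariate.

    For each design term this yields the term's population mean (intercept)
    and its interaction with the covariate (slope), with flat-prior
    Student-t posterior intervals.
    """
    cov = covariate.reindex(coefs.index)
    keep = cov.notna()
    cov = cov[keep] - cov[keep].mean()
    n = int(keep.sum())
    if n < 3:
        raise ValueError("need at least 3 participants with covariate data")
    if float(np.std(cov)) == 0:
        raise ValueError("covariate has zero variance")
    X = np.column_stack([np.ones(n), cov.to_numpy()])
    XtXinv = np.linalg.inv(X.T @ X)
    dof = n - 2
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    out = []
    for term in coefs.columns:
        y = coefs.loc[keep.index[keep], term].to_numpy()
        beta = XtXinv @ X.T @ y
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / dof
        for j, label in ((0, term), (1, f"{term}:mh")):
            se = float(np.sqrt(sigma2 * XtXinv[j, j]))
            mean = float(beta[j])
            tail = 2.0 * float(stats.t.sf(abs(mean) / se, dof)) if se > 0 else 0.0
            out.append(dict(effect=label, mean=mean, se=se,
                            lower=mean - tcrit * se, upper=mean + tcrit * se,
                            tail_p=tail,
                            significant=bool(abs(mean) > tcrit * se), n=n))
    return pd.DataFrame(out)


def moderation_scan(
    trials: pd.DataFrame,
    mh_table: pd.DataFrame,
    which: str = "response",
    q: float = 0.05,
    penalty: float = 1.0,
) -> dict:
    """Mental-health moderation of the Pavlovian bias, one model per
    covariate, BH-corrected across covariates.

    The primary test per covariate is the reward x covariate interaction
    (``reward:mh``). Returns a dict with the full effect table (all terms,
    all covariates), the primary-term table with BH decisions, and the
    adjusted credible level the reported intervals use.
    """
    design = build_design(trials)
    coefs = participant_coefficients(
        design, "response" if which == "response" else "rt", penalty)
    covariates = [c for c in mh_table.columns if c != "participant_id"]
    mh = mh_table.set_index("participant_id")
    primary_p, per_cov = [], {}
    for name in covariates:
        est = _second_level(coefs, mh[name])
        per_cov[name] = est
        primary_p.append(
            float(est.loc[est["effect"] == "reward:mh", "tail_p"].iloc[0]))
    reject, p_adj = bh_adjust(primary_p, q)
    # BH-adjusted credible level: intervals re-widened to match the largest
    # rejected raw tail probability (or q/m when nothing is rejected)
    m = len(covariates)
    p_crit = max((p for p, rej in zip(primary_p, reject) if rej),
                 default=q / m)
    level_adj = 1.0 - p_crit
    frames = []
    for name in covariates:
        est = _second_level(coefs, mh[name], level=level_adj)
        est.insert(0, "covariate", name)
        frames.append(est)
    effects = pd.concat(frames, ignore_index=True)
    primary = effects[effects["effect"] == "reward:mh"].copy()
    primary["tail_p_raw"] = primary_p
    primary["p_bh"] = p_adj
    primary["bh_significant"] = reject
    return dict(effects=effects, primary=primary.reset_index(drop=True),
                interval_level=level_adj)


def correlate_with_mh(values: pd.Series, mh_table: pd.DataFrame,
                      q: float = 0.05) -> pd.DataFrame:
    """Pearson correlations of a per-participant quantity with every
    covariate, BH-corrected across covariates."""
    mh = mh_table.set_index("participant_id")
    rows = []
    for name in mh.columns:
        paired = pd.concat([values, mh[name]], axis=1, join="inner").dropna()
        if len(paired) < 3:
            raise ValueError(f"covariate {name!r}: fewer than 3 pairs")
        r, p = stats.pearsonr(paired.iloc[:, 0], paired.iloc[:, 1])
        rows.append(dict(covariate=name, r=float(r), p=float(p),
                         n=len(paired)))
    out = pd.DataFrame(rows)
    reject, p_adj = bh_adjust(out["p"].to_numpy(), q)
    out["p_bh"] = p_adj
    out["bh_significant"] = reject
    return out
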