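"""The nested Rescorla-Wagner model family M0-M5 for the go/no-go task.

All six models learn cue-specific action values Q(s, a) by delta-rule
updates from binary reward feedback and choose between go and no-go through
a softmax over action weights w(s, a). The nested additions are:

* M0 - plain Rescorla-Wagner: w = Q, parameters (alpha, tau).
* M1 - adds irreducible noise xi, a lapse term mixing the softmax policy
  with uniform responding: p = softmax * (1 - xi) + xi / 2.
* M2 - adds a go bias b, a constant increment to the go action weight.
* M3 - adds the Pavlovian cue-response bias pi: the go weight gains
  pi * V(s) where V(s) is +1 for immediate-reward cues and -1 for
  delayed-reward cues. This is the hypothesised intertemporal Pavlovian
  bias parameter.
* M4 - instead of pi, a learning bias: the learning rate is alpha0 when a
  go response earned an immediate reward or a no-go response earned a
  delayed reward, and alpha1 otherwise (including all no-reward outcomes).
* M5 - both the cue-response bias and the learning bias.

Each model doubles as a likelihood evaluator over observed sessions and as
a generative agent for simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .task import CONDITIONS, CUE_VALUE, TaskSchedule, condition_components, resolve_feedback

GO, NOGO = 1, 0
#: obtained-outcome timing codes for the learning-bias rule
OBT_IMMEDIATE, OBT_DELAYED, OBT_NONE = 0, 1, 2

#: parameter boxes on the natural scale
BOUNDS = {
    "alpha": (0.0, 1.0),
    "alpha0": (0.0, 1.0),
    "alpha1": (0.0, 1.0),
    "tau": (0.0, 50.0),
    "xi": (0.0, 1.0),
    "b": (-3.0, 3.0),
    "pi": (-3.0, 3.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Identity and active components of one model in the nested family."""

    id: str
    has_noise: bool = False
    has_go_bias: bool = False
    has_cue_response_bias: bool = False
    has_learning_bias: bool = False

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["alpha0", "alpha1"] if self.has_learning_bias else ["alpha"]
        names.append("tau")
        if self.has_noise:
            names.append("xi")
        if self.has_go_bias:
            names.append("b")
        if self.has_cue_response_bias:
            names.append("pi")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [BOUNDS[name] for name in self.param_names]


MODELS: dict[str, ModelSpec] = {
    "M0": ModelSpec("M0"),
    "M1": ModelSpec("M1", has_noise=True),
    "M2": ModelSpec("M2", has_noise=True, has_go_bias=True),
    "M3": ModelSpec("M3", has_noise=True, has_go_bias=True,
                    has_cue_response_bias=True),
    "M4": ModelSpec("M4", has_noise=True, has_go_bias=True,
                    has_learning_bias=True),
    "M5": ModelSpec("M5", has_noise=True, has_go_bias=True,
                    has_cue_response_bias=True, has_learning_bias=True),
}


@dataclass
class ModelParams:
    """Full parameter vector; inactive components sit at neutral values."""

    alpha: float = 0.0
    tau: float = 0.0
    xi: float = 0.0
    b: float = 0.0
    pi: float = 0.0
    alpha0: float | None = None  # default to alpha when learning bias off
    alpha1: float | None = None

    def resolved(self, spec: ModelSpec) -> "ModelParams":
        """Fill neutral values for the components ``spec`` does not use."""
        p = replace(self)
        if not spec.has_learning_bias:
            p.alpha0 = p.alpha1 = p.alpha
        else:
            if p.alpha0 is None or p.alpha1 is None:
                raise ValueError(f"{spec.id} requires alpha0 and alpha1")
        if not spec.has_noise:
            p.xi = 0.0
        if not spec.has_go_bias:
            p.b = 0.0
        if not spec.has_cue_response_bias:
            p.pi = 0.0
        return p

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([getattr(self, n) for n in spec.param_names], float)

    @classmethod
    def from_vector(cls, x, spec: ModelSpec) -> "ModelParams":
        p = cls()
        for name, value in zip(spec.param_names, np.asarray(x, float)):
            setattr(p, name, float(value))
        if spec.has_learning_bias:
            p.alpha = float(0.5 * (p.alpha0 + p.alpha1))
        return p.resolved(spec)


# ---------------------------------------------------------------------------
# elementary operations (reference implementations; the session-level
# likelihood and simulator run through jit-compiled kernels below)
# ---------------------------------------------------------------------------

def update_q(q: float, r: float, alpha_eff: float) -> float:
    """Delta-rule update of a single action value toward reward r in {0, 1}."""
    if not 0.0 <= alpha_eff <= 1.0:
        raise ValueError("learning rate must lie in [0, 1]")
    return q + alpha_eff * (r - q)


def effective_learning_rate(
    action: str, outcome_timing: str, params: ModelParams, spec: ModelSpec,
) -> float:
    """Learning rate applied after a trial.

    Under the learning bias, alpha0 applies when a go response obtained an
    immediate reward or a no-go response obtained a delayed reward; alpha1
    applies otherwise, including when no reward was obtained.
    """
    p = params.resolved(spec)
    if not spec.has_learning_bias:
        return p.alpha
    favoured = (action == "go" and outcome_timing == "immediate") or (
        action == "nogo" and outcome_timing == "delayed")
    return p.alpha0 if favoured else p.alpha1


def action_weight(
    action: str, q: float, params: ModelParams, V_s: float, spec: ModelSpec,
) -> float:
    """Action weight: the go weight gains the go bias and pi * V(s)."""
    p = params.resolved(spec)
    if action == "go":
        return q + p.b + p.pi * V_s
    return q


def choice_prob_go(w_go: float, w_nogo: float, tau: float, xi: float) -> float:
    """Softmax go probability with a lapse mixture.

    p(go) = softmax(tau * w)_go * (1 - xi) + xi / 2, which is bounded within
    [xi / 2, 1 - xi / 2] and sums to 1 with its no-go counterpart.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    m = max(w_go, w_nogo)
    eg = np.exp(tau * (w_go - m))
    en = np.exp(tau * (w_nogo - m))
    return float(eg / (eg + en) * (1.0 - xi) + xi / 2.0)


# ---------------------------------------------------------------------------
# jit kernels
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-12  # guards log(0) in xi-free models only


@njit(cache=True)
def _loglik_kernel(cond, act, rew, obt, V, alpha0, alpha1, tau, xi, b, pi):
    Q = np.zeros((4, 2))
    ll = 0.0
    for t in range(cond.shape[0]):
        c = cond[t]
        w_go = Q[c, 1] + b + pi * V[c]
        w_nogo = Q[c, 0]
        m = max(w_go, w_nogo)
        eg = np.exp(tau * (w_go - m))
        en = np.exp(tau * (w_nogo - m))
        p_go = eg / (eg + en) * (1.0 - xi) + xi / 2.0
        p = p_go if act[t] == 1 else 1.0 - p_go
        if p < _LOG_FLOOR:
            p = _LOG_FLOOR
        ll += np.log(p)
        if (act[t] == 1 and obt[t] == 0) or (act[t] == 0 and obt[t] == 1):
            a_eff = alpha0
        else:
            a_eff = alpha1
        Q[c, act[t]] += a_eff * (rew[t] - Q[c, act[t]])
    return ll


@njit(cache=True)
def _simulate_kernel(cond, valid, go_req, timing, V, u,
                     alpha0, alpha1, tau, xi, b, pi):
    n = cond.shape[0]
    act = np.empty(n, np.int64)
    rew = np.empty(n, np.float64)
    correct = np.empty(n, np.int64)
    p_go_trace = np.empty(n, np.float64)
    Q = np.zeros((4, 2))
    for t in range(n):
        c = cond[t]
        w_go = Q[c, 1] + b + pi * V[c]
        w_nogo = Q[c, 0]
        m = max(w_go, w_nogo)
        eg = np.exp(tau * (w_go - m))
        en = np.exp(tau * (w_nogo - m))
        p_go = eg / (eg + en) * (1.0 - xi) + xi / 2.0
        p_go_trace[t] = p_go
        a = 1 if u[t] < p_go else 0
        act[t] = a
        ok = 1 if a == go_req[c] else 0
        correct[t] = ok
        r = 1.0 if ok == valid[t] else 0.0  # probabilistic feedback
        rew[t] = r
        obt = timing[c] if r > 0 else 2
        if (a == 1 and obt == 0) or (a == 0 and obt == 1):
            a_eff = alpha0
        else:
            a_eff = alpha1
        Q[c, a] += a_eff * (r - Q[c, a])
    return act, rew, correct, p_go_trace


# per-condition constants aligned with task.CONDITIONS
_GO_REQUIRED = np.array(
    [1 if condition_components(c)[0] == "go" else 0 for c in CONDITIONS],
    dtype=np.int64)
_TIMING = np.array(
    [0 if condition_components(c)[1] == "immediate" else 1 for c in CONDITIONS],
    dtype=np.int64)
_V = np.array(
    [CUE_VALUE[condition_components(c)[1]] for c in CONDITIONS], dtype=np.float64)


def session_arrays(session: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Encode a session table for the jit kernels.

    Returns (condition index, action, reward, obtained-outcome timing).
    """
    if len(session) == 0:
        raise ValueError("session is empty")
    lookup = {c: i for i, c in enumerate(CONDITIONS)}
    cond = session["condition"].map(lookup).to_numpy(np.int64)
    act = (session["response"] == "go").to_numpy(np.int64)
    rew = (session["outcome"] == "reward").to_numpy(np.float64)
    obt = np.where(rew > 0, _TIMING[cond], OBT_NONE).astype(np.int64)
    return cond, act, rew, obt


def loglik_arrays(x, spec: ModelSpec, cond, act, rew, obt) -> float:
    """Session log-likelihood from a parameter vector in ``spec`` order."""
    p = ModelParams.from_vector(x, spec)
    return float(_loglik_kernel(cond, act, rew, obt, _V,
                                p.alpha0, p.alpha1, p.tau, p.xi, p.b, p.pi))


def session_loglik(params: ModelParams, spec: ModelSpec,
                   session: pd.DataFrame) -> float:
    """Log-likelihood of the observed go/no-go responses under one model.

    The latent state evolves with the observed actions and outcomes using
    the same update rules as simulation.
    """
    cond, act, rew, obt = session_arrays(session)
    p = params.resolved(spec)
    return float(_loglik_kernel(cond, act, rew, obt, _V,
                                p.alpha0, p.alpha1, p.tau, p.xi, p.b, p.pi))


def simulate_agent(
    params: ModelParams,
    spec: ModelSpec,
    schedule: TaskSchedule,
    seed: int,
    participant_id: str | int = 0,
    rt_sampler=None,
) -> pd.DataFrame:
    """Simulate one agent's session on a schedule.

    Per trial: compute p(go), draw the action, score correctness against the
    required action, resolve probabilistic feedback, and update the taken
    action's value with the effective learning rate. ``rt_sampler``, if
    given, is called as ``rt_sampler(condition, correct, rng)`` for go
    responses to attach a response time in ms.
    """
    p = params.resolved(spec)
    rng = np.random.default_rng(seed)
    cond = schedule.condition_idx
    valid = schedule.feedback_valid.astype(np.int64)
    u = rng.random(len(schedule))
    act, rew, correct, _ = _simulate_kernel(
        cond, valid, _GO_REQUIRED, _TIMING, _V, u,
        p.alpha0, p.alpha1, p.tau, p.xi, p.b, p.pi)
    df = schedule.to_frame()
    df.insert(0, "participant_id", participant_id)
    df = df.rename(columns={"index": "trial"})
    df["response"] = np.where(act == 1, "go", "nogo")
    df["correct"] = correct.astype(bool)
    df["outcome"] = np.where(rew > 0, "reward", "no-reward")
    if rt_sampler is not None:
        rt = np.full(len(df), np.nan)
        for i in np.flatnonzero(act == 1):
            rt[i] = rt_sampler(df["condition"].iat[i], bool(correct[i]), rng)
        df["rt_ms"] = rt
    else:
        df["rt_ms"] = np.nan
    return df


def enumerate_sequence_probs(
    params: ModelParams, spec: ModelSpec, schedule: TaskSchedule,
) -> np.ndarray:
    """Probability of every possible response sequence on a short schedule.

    Brute-force enumeration over the 2^T go/no-go sequences with feedback
    fixed by the schedule's validity flags; used to verify that the
    session likelihood defines a proper probability distribution.
    """
    T = len(schedule)
    if T > 12:
        raise ValueError("enumeration is exponential; use T <= 12")
    base = schedule.to_frame().rename(columns={"index": "trial"})
    probs = np.empty(2 ** T)
    for m in range(2 ** T):
        acts = [(m >> t) & 1 for t in range(T)]
        df = base.copy()
        df["response"] = ["go" if a else "nogo" for a in acts]
        df["correct"] = [
            a == (1 if req == "go" else 0)
            for a, req in zip(acts, df["required_action"])
        ]
        df["outcome"] = [
            resolve_feedback(bool(c), bool(v))
            for c, v in zip(df["correct"], df["feedback_valid"])
        ]
        probs[m] = np.exp(session_loglik(params, spec, df))
    return probs
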