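"""Intertemporal go/no-go task schedules and probabilistic feedback.

The task crosses the required instrumental action (go / no-go) with the
timing of the reward available for a correct response (immediate / delayed),
giving four conditions. Each condition is presented a fixed number of times
in pseudorandom order (no condition more than ``max_run`` times in a row),
and feedback is only congruent with response correctness on a fixed fraction
of trials (probabilistic feedback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Condition labels, ordered. The first two require a go response; conditions
#: 0 and 2 pay an immediate reward, 1 and 3 a delayed reward.
CONDITIONS = ("go-immediate", "go-delayed", "nogo-immediate", "nogo-delayed")

#: Pavlovian cue value V(s): +1 for immediate-reward cues, -1 for delayed.
CUE_VALUE = {"immediate": 1.0, "delayed": -1.0}

N_BLOCKS = 4


def condition_components(condition: str) -> tuple[str, str]:
    """Split a condition label into (required_action, reward_timing)."""
    action, timing = condition.split("-")
    if action not in ("go", "nogo") or timing not in ("immediate", "delayed"):
        raise ValueError(f"unknown condition label: {condition!r}")
    return action, timing


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: position, condition, block and feedback validity."""

    index: int  # 1-based
    condition: str
    block: int
    feedback_valid: bool

    @property
    def required_action(self) -> str:
        return condition_components(self.condition)[0]

    @property
    def reward_timing(self) -> str:
        return condition_components(self.condition)[1]


@dataclass
class TaskSchedule:
    """An ordered trial list with its generating constraints."""

    trials: list[TrialSpec]
    n_per_condition: int
    max_run: int
    seed: int
    feedback_validity: float = 0.8

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    @property
    def condition_idx(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(CONDITIONS)}
        return np.array([lookup[t.condition] for t in self.trials], dtype=np.int64)

    @property
    def feedback_valid(self) -> np.ndarray:
        return np.array([t.feedback_valid for t in self.trials], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                index=t.index,
                block=t.block,
                condition=t.condition,
                required_action=t.required_action,
                reward_timing=t.reward_timing,
                feedback_valid=t.feedback_valid,
            )
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, n_per_condition: int | None = None,
        max_run: int = 2, seed: int = 0, feedback_validity: float = 0.8,
    ) -> "TaskSchedule":
        if n_per_condition is None:
            n_per_condition = int(df["condition"].value_counts().max())
        trials = [
            TrialSpec(int(r.index), str(r.condition), int(r.block), bool(r.feedback_valid))
            for r in df.itertuples(index=False)
        ]
        return cls(trials, n_per_condition, max_run, seed, feedback_validity)


def _pseudorandom_order(
    n_per_condition: int, max_run: int, rng: np.random.Generator,
    max_restarts: int = 10_000,
) -> list[int]:
    """Draw a condition order with no run longer than ``max_run``.

    Constrained sequential sampling: each trial's condition is drawn with
    probability proportional to its remaining count, restricted to conditions
    that do not extend the current run past ``max_run``. Dead ends (only the
    running condition has trials left) trigger a restart; they are rare for
    the task's balanced designs.
    """
    n_cond = len(CONDITIONS)
    n_total = n_cond * n_per_condition
    for _ in range(max_restarts):
        remaining = [n_per_condition] * n_cond
        order: list[int] = []
        run_cond, run_len = -1, 0
        ok = True
        u = rng.random(n_total)
        for t in range(n_total):
            weights = list(remaining)
            if run_len >= max_run and run_cond >= 0:
                weights[run_cond] = 0
            total = sum(weights)
            if total == 0:
                ok = False
                break
            x = u[t] * total
            c = 0
            acc = weights[0]
            while x >= acc:
                c += 1
                acc += weights[c]
            order.append(c)
            remaining[c] -= 1
            if c == run_cond:
                run_len += 1
            else:
                run_cond, run_len = c, 1
        if ok:
            return order
    raise ValueError(
        f"could not satisfy max_run={max_run} with "
        f"n_per_condition={n_per_condition} after {max_restarts} restarts"
    )


def generate_schedule(
    n_per_condition: int,
    max_run: int = 2,
    feedback_validity: float = 0.8,
    seed: int = 0,
) -> TaskSchedule:
    """Generate a pseudorandom task schedule.

    Parameters
    ----------
    n_per_condition
        Presentations of each of the four conditions (the full task uses 50,
        i.e. 200 trials).
    max_run
        Longest permitted run of one condition (the task uses 2).
    feedback_validity
        Probability that a trial's feedback is congruent with response
        correctness (the task uses 0.8). Validity is drawn independently per
        trial.
    seed
        Seed for both the condition order and the validity draws; identical
        inputs reproduce the identical schedule.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be a positive integer")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    if not 0.0 <= feedback_validity <= 1.0:
        raise ValueError("feedback_validity must be a probability")
    n_total = len(CONDITIONS) * n_per_condition
    if n_total % N_BLOCKS != 0:
        raise ValueError(
            f"total trials ({n_total}) must divide into {N_BLOCKS} equal blocks"
        )
    rng = np.random.default_rng(seed)
    order = _pseudorandom_order(n_per_condition, max_run, rng)
    valid = rng.random(n_total) < feedback_validity
    per_block = n_total // N_BLOCKS
    trials = [
        TrialSpec(
            index=i + 1,
            condition=CONDITIONS[c],
            block=i // per_block + 1,
            feedback_valid=bool(valid[i]),
        )
        for i, c in enumerate(order)
    ]
    return TaskSchedule(trials, n_per_condition, max_run, seed, feedback_validity)


def resolve_feedback(response_correct: bool, feedback_valid: bool) -> str:
    """Map correctness and validity to the displayed outcome.

    On valid trials the outcome matches correctness (correct -> reward); on
    invalid trials it is reversed.
    """
    shown_correct = response_correct if feedback_valid else not response_correct
    return "reward" if shown_correct else "no-reward"


def validate_schedule(schedule: TaskSchedule) -> list[str]:
    """Return every condition-count and run-length violation (empty = valid)."""
    violations: list[str] = []
    conds = list(schedule.conditions)
    for c in CONDITIONS:
        n = conds.count(c)
        if n != schedule.n_per_condition:
            violations.append(
                f"count: condition {c!r} occurs {n} times, "
                f"expected {schedule.n_per_condition}"
            )
    run_cond, run_start, run_len = None, 0, 0
    for i, c in enumerate(conds + [None]):  # sentinel flushes the last run
        if c == run_cond:
            run_len += 1
        else:
            if run_cond is not None and run_len > schedule.max_run:
                violations.append(
                    f"run: condition {run_cond!r} repeats {run_len} times "
                    f"at trials {run_start + 1}-{run_start + run_len} "
                    f"(max_run={schedule.max_run})"
                )
            run_cond, run_start, run_len = c, i, 1
    return violations
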