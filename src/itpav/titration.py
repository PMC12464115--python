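"""Choice titration: discount-rate scoring and the adaptive staircase.

Participants first answer the 27-item Monetary Choice Questionnaire (MCQ),
from which a hyperbolic discount rate ``k`` is scored by consistency
maximisation over the instrument's canonical candidate grid. That ``k``
seeds an adaptive staircase offering "EUR X today" (X an even integer in
[0, 28]) against a fixed "EUR 28 in 120 days"; the offer steps down after an
immediate choice and up after a delayed choice until six consecutive offers
span at most EUR 2. The converged offer is the participant's
preference-matched immediate reward; its reverse coding (29 - X) is the
impatience score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DELAYED_AMOUNT = 28.0
DELAY_DAYS = 120.0

#: The standard 27 MCQ items as (immediate amount, delayed amount, delay in
#: days). Shipped as a packaged fixture reproducing the canonical instrument.
MCQ_ITEMS: tuple[tuple[float, float, float], ...] = (
    (54, 55, 117), (55, 75, 61), (19, 25, 53), (31, 85, 7), (14, 25, 19),
    (47, 50, 160), (15, 35, 13), (25, 60, 14), (78, 80, 162), (40, 55, 62),
    (11, 30, 7), (67, 75, 119), (34, 35, 186), (27, 50, 21), (69, 85, 91),
    (49, 60, 89), (80, 85, 157), (24, 35, 29), (33, 80, 14), (28, 30, 179),
    (34, 50, 30), (25, 30, 80), (41, 75, 20), (54, 60, 111), (54, 80, 30),
    (22, 25, 136), (20, 55, 7),
)


def hyperbolic_value(amount: float, delay_days: float, k: float) -> float:
    """Present value of a delayed amount under hyperbolic discounting."""
    return amount / (1.0 + k * delay_days)


def _implied_k(immediate: float, delayed: float, delay: float) -> float:
    """Discount rate at which the two options of an item are indifferent."""
    return (delayed / immediate - 1.0) / delay


def candidate_k_grid(
    item_bank: tuple[tuple[float, float, float], ...] = MCQ_ITEMS,
) -> np.ndarray:
    """The canonical 10-value candidate grid for MCQ consistency scoring.

    The 27 items reduce to 9 indifference discount-rate ranks (items within a
    rank agree to within ~2%, so ranks are clustered on a log scale); the
    grid is the two extreme ranks plus the geometric means of adjacent ranks
    (9 ranks -> 10 candidates).
    """
    implied = np.array([_implied_k(*item) for item in item_bank])
    clusters: dict[float, list[float]] = {}
    for k in implied:
        clusters.setdefault(round(np.log10(k), 1), []).append(k)
    ranks = np.sort([np.exp(np.mean(np.log(v))) for v in clusters.values()])
    mids = np.sqrt(ranks[:-1] * ranks[1:])
    return np.concatenate([[ranks[0]], mids, [ranks[-1]]])


def score_mcq(
    choices,
    item_bank: tuple[tuple[float, float, float], ...] = MCQ_ITEMS,
) -> float:
    """Score MCQ choices as the most choice-consistent candidate ``k``.

    Parameters
    ----------
    choices
        Sequence of booleans aligned with ``item_bank``; True means the
        immediate option was chosen.

    Returns
    -------
    The candidate ``k`` maximising the number of choices consistent with
    hyperbolic discounting at that rate; ties are broken by the geometric
    mean of the tied candidates.
    """
    choices = np.asarray(choices, dtype=bool)
    if choices.shape[0] != len(item_bank):
        raise ValueError(
            f"expected {len(item_bank)} choices, got {choices.shape[0]}"
        )
    grid = candidate_k_grid(item_bank)
    items = np.asarray(item_bank, dtype=float)
    imm, dly, days = items[:, 0], items[:, 1], items[:, 2]
    # predicted immediate choice at each candidate k (rows: candidates)
    predicted = imm[None, :] > dly[None, :] / (1.0 + grid[:, None] * days[None, :])
    consistency = (predicted == choices[None, :]).sum(axis=1)
    best = consistency == consistency.max()
    return float(np.exp(np.mean(np.log(grid[best]))))


def starting_amount(
    k: float,
    delayed_amount: float = DELAYED_AMOUNT,
    delay: float = DELAY_DAYS,
) -> int:
    """Staircase starting offer: the hyperbolic present value of the delayed
    reward, rounded to the nearest even integer (ties down), clipped to
    [0, delayed_amount]."""
    if k < 0:
        raise ValueError("discount rate k must be non-negative")
    pv = hyperbolic_value(delayed_amount, delay, k)
    lower = 2 * int(np.floor(pv / 2.0))
    upper = lower + 2
    even = lower if (pv - lower) <= (upper - pv) else upper
    return int(np.clip(even, 0, delayed_amount))


@dataclass
class TitrationResult:
    """Outcome of one adaptive staircase run."""

    matched_amount: int | None
    n_trials: int
    converged: bool
    excluded_reason: str  # none | no-stability | prefers-zero
    trajectory: list[int] = field(default_factory=list)
    choices: list[str] = field(default_factory=list)


def run_titration(
    choose,
    start: int,
    step: int = 2,
    stability_window: int = 6,
    stability_span: int = 2,
    max_trials: int = 50,
) -> TitrationResult:
    """Run the adaptive staircase against a choice function.

    Parameters
    ----------
    choose
        Callable mapping an immediate offer (euros) to ``"immediate"`` or
        ``"delayed"``.
    start
        First offer; must be an even integer within [0, 28].

    Notes
    -----
    The offer decreases by ``step`` after an immediate choice and increases
    after a delayed choice, clipped to [0, 28]. The run converges when the
    last ``stability_window`` offers span at most ``stability_span`` euros;
    the matched amount is the rounded mean of that window. Choosing the EUR 0
    offer triggers one confirmation trial; a repeated EUR 0 preference marks
    the participant as excluded (``prefers-zero``). Failing to stabilise
    within ``max_trials`` marks ``no-stability``. The confirmation trial
    counts toward ``max_trials``.
    """
    if start % 2 != 0 or not 0 <= start <= DELAYED_AMOUNT:
        raise ValueError("start must be an even integer within [0, 28]")
    offers: list[int] = []
    picks: list[str] = []
    offer = int(start)
    zero_streak = 0
    while len(offers) < max_trials:
        choice = choose(offer)
        if choice not in ("immediate", "delayed"):
            raise ValueError(f"choice function returned {choice!r}")
        offers.append(offer)
        picks.append(choice)
        if offer == 0 and choice == "immediate":
            zero_streak += 1
            if zero_streak >= 2:  # confirmed preference for nothing now
                return TitrationResult(None, len(offers), False,
                                       "prefers-zero", offers, picks)
            continue  # confirmation trial repeats the EUR 0 offer
        zero_streak = 0
        if len(offers) >= stability_window:
            window = offers[-stability_window:]
            if max(window) - min(window) <= stability_span:
                matched = int(round(float(np.mean(window))))
                return TitrationResult(matched, len(offers), True,
                                       "none", offers, picks)
        delta = -step if choice == "immediate" else step
        offer = int(np.clip(offer + delta, 0, DELAYED_AMOUNT))
    return TitrationResult(None, len(offers), False, "no-stability",
                           offers, picks)


def impatience_score(matched_amount: int) -> int:
    """Reverse-code a matched amount in [1, 28] to an impatience score
    (1-28, higher = more impatient)."""
    if not 1 <= matched_amount <= 28:
        raise ValueError("matched_amount must lie in [1, 28]")
    return 29 - int(matched_amount)


@dataclass
class DiscountAgent:
    """Hyperbolic discounter that answers MCQ items and staircase offers.

    ``choice_noise`` is the logistic temperature on present-value
    differences; 0 gives a deterministic (indifference-point) chooser.
    """

    k: float
    choice_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def prefers_immediate(
        self, immediate: float, delayed: float, delay: float,
        rng: np.random.Generator | None = None,
    ) -> bool:
        diff = immediate - hyperbolic_value(delayed, delay, self.k)
        if self.choice_noise <= 0 or rng is None:
            return diff > 0
        p = 1.0 / (1.0 + np.exp(-diff / self.choice_noise))
        return bool(rng.random() < p)

    def mcq_choices(
        self, item_bank=MCQ_ITEMS, rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        return np.array([
            self.prefers_immediate(i, d, days, rng)
            for i, d, days in item_bank
        ])

    def staircase_chooser(self, rng: np.random.Generator | None = None):
        def choose(offer: float) -> str:
            imm = self.prefers_immediate(offer, DELAYED_AMOUNT, DELAY_DAYS, rng)
            return "immediate" if imm else "delayed"
        return choose
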