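"""Lottery choice-set construction and its analytic identifiability properties.

The task is a two-option risky choice: on every trial the decision maker
picks between a certain $5 and a single risky lottery (one win probability,
one dollar amount, $0 otherwise). The standard design crosses five win
probabilities with seven amounts, giving 35 trials per condition.

Money is held as integer cents and probabilities as integer percent so that
expected values and earnings sums are exact; public accessors return floats
in dollars.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field

import pandas as pd

#: win probabilities of the standard design grid
GRID_PROBABILITIES = (0.10, 0.25, 0.50, 0.75, 0.90)
#: dollar amounts of the standard design grid
GRID_AMOUNTS = (5, 10, 20, 30, 40, 50, 100)
#: the certain option: $5 for sure
SAFE_AMOUNT = 5.0


class Condition(str, enum.Enum):
    """Experimental conditions of the dyadic risky-choice study."""

    BASELINE = "Baseline"
    IDENTICAL = "Identical"
    OPPOSITE = "Opposite"
    OBSERVED_IDENTICAL = "ObservedIdentical"
    UNOBSERVED_IDENTICAL = "UnobservedIdentical"
    OBSERVED_OPPOSITE = "ObservedOpposite"
    UNOBSERVED_OPPOSITE = "UnobservedOpposite"
    PREDICTED_FRIEND = "PredictedFriend"


#: conditions whose choices pit the decision maker's outcome against the
#: friend's (the unchosen option goes to the friend)
OPPOSITE_FAMILY = frozenset(
    {Condition.OPPOSITE, Condition.OBSERVED_OPPOSITE, Condition.UNOBSERVED_OPPOSITE}
)
#: conditions modelled with the two-parameter (alpha, beta) utility model
BASELINE_FAMILY = frozenset(
    {
        Condition.BASELINE,
        Condition.IDENTICAL,
        Condition.OBSERVED_IDENTICAL,
        Condition.UNOBSERVED_IDENTICAL,
        Condition.PREDICTED_FRIEND,
    }
)


@dataclass(frozen=True)
class Lottery:
    """A prospect paying ``amount`` dollars with probability ``p_win``, else $0.

    The certain option is ``Lottery(p_win=1.0, amount=5)``.
    """

    p_win: float
    amount: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_win <= 1.0):
            raise ValueError(f"p_win must be in (0, 1], got {self.p_win}")
        if self.amount <= 0:
            raise ValueError(f"amount must be positive, got {self.amount}")

    @property
    def _percent(self) -> int:
        return round(self.p_win * 100)

    @property
    def _cents(self) -> int:
        return round(self.amount * 100)

    @property
    def expected_value(self) -> float:
        """Expected value in dollars; exact for grid lotteries."""
        num = self._percent * self._cents  # percent x cents
        if num % 100 == 0:
            return (num // 100) / 100.0
        return self.p_win * self.amount


SAFE_LOTTERY = Lottery(p_win=1.0, amount=SAFE_AMOUNT)


@dataclass(frozen=True)
class ChoiceTrial:
    """One safe-vs-risky decision; ``risky_side`` records screen placement."""

    trial_index: int
    safe: Lottery
    risky: Lottery
    risky_side: str  # "left" or "right"

    def __post_init__(self) -> None:
        if self.safe.p_win != 1.0:
            raise ValueError("safe option must be certain (p_win = 1)")
        if self.risky.p_win >= 1.0:
            raise ValueError("risky option must be uncertain (p_win < 1)")
        if self.risky_side not in ("left", "right"):
            raise ValueError(f"risky_side must be 'left' or 'right', got {self.risky_side!r}")


@dataclass
class ChoiceSet:
    """An ordered set of trials presented within one condition."""

    condition: Condition
    trials: list[ChoiceTrial] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a long table (one row per trial)."""
        return pd.DataFrame(
            {
                "condition": self.condition.value,
                "trial_index": [t.trial_index for t in self.trials],
                "p_win": [t.risky.p_win for t in self.trials],
                "amount": [t.risky.amount for t in self.trials],
                "safe_amount": [t.safe.amount for t in self.trials],
                "risky_side": [t.risky_side for t in self.trials],
            }
        )


def build_choice_set(condition: Condition | str, seed: int) -> ChoiceSet:
    """Build the standard 35-trial choice set for one condition.

    Every (probability, amount) cell of the design grid appears exactly once.
    Trial order is a seeded permutation, and the risky option's screen side is
    counterbalanced as close to half/half as the odd trial count allows
    (18/17), with the assignment shuffled by the same seed.
    """
    condition = Condition(condition)
    pairs = [(p, a) for p in GRID_PROBABILITIES for a in GRID_AMOUNTS]
    rng = random.Random(seed)
    rng.shuffle(pairs)
    n = len(pairs)
    sides = ["left"] * ((n + 1) // 2) + ["right"] * (n // 2)
    rng.shuffle(sides)
    trials = [
        ChoiceTrial(
            trial_index=i,
            safe=SAFE_LOTTERY,
            risky=Lottery(p_win=p, amount=float(a)),
            risky_side=side,
        )
        for i, ((p, a), side) in enumerate(zip(pairs, sides))
    ]
    return ChoiceSet(condition=condition, trials=trials, seed=seed)


def indifference_alpha(risky: Lottery, safe: Lottery) -> float | None:
    """Risk exponent at which ``risky`` and ``safe`` have equal power utility.

    With utility p * v**alpha, the crossing point for a certain amount s is
    alpha* = ln(1/p) / ln(v/s), defined only when v > s. For v <= s the risky
    option is dominated — never preferred at any positive alpha — and None is
    returned. Above the largest alpha* in a choice set, noise-free choice
    vectors stop changing, which bounds the recoverable range of the exponent.
    """
    if safe.p_win != 1.0:
        raise ValueError("safe option must be certain (p_win = 1)")
    import math

    if risky.amount <= safe.amount:
        return None
    return math.log(1.0 / risky.p_win) / math.log(risky.amount / safe.amount)


def max_recoverable_alpha(choice_set: ChoiceSet) -> float:
    """Largest indifference alpha over the set's trials.

    For the standard design this is ln(10)/ln(2) ~ 3.32, from the 10% chance
    of $10 lottery; exponents above it produce identical deterministic
    behaviour and cannot be told apart by the task.
    """
    if not choice_set.trials:
        raise ValueError("choice set is empty")
    alphas = [
        a
        for t in choice_set.trials
        if (a := indifference_alpha(t.risky, t.safe)) is not None
    ]
    if not alphas:
        raise ValueError("no trial has an indifference point: all risky options dominated")
    return max(alphas)


def max_possible_earnings(choice_set: ChoiceSet) -> float:
    """Earnings ceiling: sum over trials of the higher expected value.

    Exact to the cent ($662.50 for the standard set).
    """
    if not choice_set.trials:
        raise ValueError("choice set is empty")
    total_cents = sum(
        max(round(t.safe.expected_value * 100), round(t.risky.expected_value * 100))
        for t in choice_set.trials
    )
    return total_cents / 100.0


def deterministic_choice_vector(choice_set: ChoiceSet, alpha: float) -> tuple[bool, ...]:
    """Noise-free choices: risky iff its power utility exceeds the safe one.

    Used to enumerate identifiability: two exponents are behaviourally
    distinguishable exactly when their vectors differ.
    """
    out = []
    for t in choice_set.trials:
        eu_r = t.risky.p_win * t.risky.amount**alpha
        eu_s = t.safe.amount**alpha
        out.append(eu_r > eu_s)
    return tuple(out)
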