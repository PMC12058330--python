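"""Model-free behavioural measures per participant x condition.

Two summaries complement the fitted risk exponent: the raw proportion of
risky choices, and simulated earnings — the sum of expected values of the
chosen options (no lottery outcomes are sampled), reported both in dollars
and as a proportion of the set's earnings ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .models import ChoiceRecord
from .task import ChoiceSet, Condition, max_possible_earnings


@dataclass
class BehaviorSummary:
    participant_id: str
    condition: Condition
    prop_risky: float
    earnings: float
    earnings_prop: float


def proportion_risky(records: Sequence[ChoiceRecord]) -> float:
    """Fraction of trials on which the risky option was chosen."""
    if not records:
        raise ValueError("records is empty")
    return sum(r.chose_risky for r in records) / len(records)


def simulated_earnings(records: Sequence[ChoiceRecord]) -> float:
    """Sum of the chosen options' expected values, exact to the cent."""
    if not records:
        raise ValueError("records is empty")
    cents = sum(
        round((r.trial.risky if r.chose_risky else r.trial.safe).expected_value * 100)
        for r in records
    )
    return cents / 100.0


def earnings_proportion(records: Sequence[ChoiceRecord], choice_set: ChoiceSet) -> float:
    """Simulated earnings as a share of the set's highest-EV ceiling."""
    if len(records) != len(choice_set.trials):
        raise ValueError(
            f"records ({len(records)}) do not align with the choice set ({len(choice_set.trials)} trials)"
        )
    got = {(r.trial.risky.p_win, r.trial.risky.amount) for r in records}
    want = {(t.risky.p_win, t.risky.amount) for t in choice_set.trials}
    if got != want:
        raise ValueError("records cover a different lottery grid than the choice set")
    return simulated_earnings(records) / max_possible_earnings(choice_set)


def summarize(
    records: Sequence[ChoiceRecord],
    choice_set: ChoiceSet,
    participant_id: str = "",
) -> BehaviorSummary:
    return BehaviorSummary(
        participant_id=participant_id,
        condition=choice_set.condition,
        prop_risky=proportion_risky(records),
        earnings=simulated_earnings(records),
        earnings_prop=earnings_proportion(records, choice_set),
    )
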