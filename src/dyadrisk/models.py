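"""Utility models, the logistic choice rule, likelihoods, and choice simulation.

Three models are supported:

``original``
    Power expected utility EU = p * v**alpha with a two-parameter
    (alpha, beta) softmax/logistic choice rule. Used for the Baseline and
    Identical-context conditions and for predicted-friend choices.

``revised``
    The social adjudication model for the Opposite context: choosing means
    assigning one option to oneself and the other to one's friend, and the
    utility of an assignment mixes own and friend expected utilities,
    EU = (1 - w) * p_self * v_self**alpha + w * p_friend * v_friend**alpha_friend,
    where w in [0, 1] is the friend-outcome weight and alpha_friend is a fixed
    per-participant constant (the exponent recovered from the participant's
    predictions of their friend's baseline choices).

``prospect``
    A gains-only prospect-theory alternative with Tversky-Kahneman
    probability weighting, kept for model-comparison harnesses.

Convention for the Opposite context: ``chose_risky`` means the risky option
was assigned to SELF (the friend implicitly receives the safe option), and
vice versa.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .task import ChoiceSet, ChoiceTrial, Lottery


class Model(str, enum.Enum):
    ORIGINAL = "original"
    REVISED = "revised"
    PROSPECT = "prospect"


@dataclass(frozen=True)
class OriginalParams:
    """Risk exponent alpha (>0) and inverse decision noise beta (>=0)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


@dataclass(frozen=True)
class SocialParams:
    """Parameters of the social adjudication model.

    ``w`` weighs the friend's expected utility against one's own;
    ``alpha_friend`` is a fixed constant, never re-fit jointly with the rest.
    """

    alpha: float
    beta: float
    w: float
    alpha_friend: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if self.alpha_friend <= 0 or not np.isfinite(self.alpha_friend):
            raise ValueError(f"alpha_friend must be finite and positive, got {self.alpha_friend}")


@dataclass(frozen=True)
class PTParams:
    """Prospect-theory parameters: exponent, weighting curvature, inverse noise."""

    alpha: float
    gamma: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0.0 < self.gamma <= 1.5):
            raise ValueError(f"gamma must be in (0, 1.5], got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed decision: the trial plus whether the risky option was chosen."""

    trial: ChoiceTrial
    chose_risky: bool


def expected_utility(lottery: Lottery, alpha: float) -> float:
    """Power expected utility p * v**alpha."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return lottery.p_win * lottery.amount**alpha


def opposite_pair_utility(self_option: Lottery, friend_option: Lottery, params: SocialParams) -> float:
    """Utility of assigning ``self_option`` to oneself and ``friend_option`` to the friend.

    A weighted average of own utility (exponent alpha) and the friend's
    utility computed under the believed friend exponent.
    """
    return (1.0 - params.w) * expected_utility(self_option, params.alpha) + params.w * expected_utility(
        friend_option, params.alpha_friend
    )


def probability_weight(p: float | np.ndarray, gamma: float) -> float | np.ndarray:
    """Tversky-Kahneman inverse-S weighting pi(p) = p^g / (p^g + (1-p)^g)^(1/g)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    p = np.asarray(p, dtype=float)
    num = p**gamma
    den = (p**gamma + (1.0 - p) ** gamma) ** (1.0 / gamma)
    out = num / den
    return float(out) if out.ndim == 0 else out


def pt_expected_utility(lottery: Lottery, params: PTParams) -> float:
    """Prospect-theory value: weighted probability applied to v**alpha (gains only)."""
    return float(probability_weight(lottery.p_win, params.gamma)) * lottery.amount**params.alpha


def p_choose_risky(eu_safe, eu_risky, beta: float):
    """Logistic choice rule P(risky) = 1 / (1 + exp(beta * (EU_safe - EU_risky))).

    Computed through a numerically stable log-sum-exp so that beta * dEU of
    several hundred (possible with $100 amounts and alpha near 2) neither
    overflows nor collapses to exactly 0 or 1 in log space.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    x = np.asarray(beta * (np.asarray(eu_safe, dtype=float) - np.asarray(eu_risky, dtype=float)))
    out = np.exp(-np.logaddexp(0.0, x))
    return float(out) if out.ndim == 0 else out


def _log_p_choice(x: np.ndarray, chose_risky: np.ndarray) -> np.ndarray:
    """log P(observed) where x = beta*(EU_safe - EU_risky); stable in both tails."""
    # log P(risky) = -log(1+e^x); log P(safe) = -log(1+e^-x)
    return np.where(chose_risky, -np.logaddexp(0.0, x), -np.logaddexp(0.0, -x))


def _trial_arrays(records: Sequence[ChoiceRecord]):
    p = np.array([r.trial.risky.p_win for r in records])
    v = np.array([r.trial.risky.amount for r in records])
    s = np.array([r.trial.safe.amount for r in records])
    y = np.array([r.chose_risky for r in records], dtype=bool)
    return p, v, s, y


def _gap_arrays(p: np.ndarray, v: np.ndarray, s: np.ndarray, model: Model, params) -> np.ndarray:
    """EU_safe - EU_risky on pre-extracted trial arrays (hot path for fitting)."""
    if model is Model.ORIGINAL:
        eu_r = p * v**params.alpha
        eu_s = s**params.alpha
    elif model is Model.REVISED:
        # risky-to-self assignment: friend receives the safe option; and vice versa
        eu_r = (1.0 - params.w) * p * v**params.alpha + params.w * s**params.alpha_friend
        eu_s = (1.0 - params.w) * s**params.alpha + params.w * p * v**params.alpha_friend
    elif model is Model.PROSPECT:
        eu_r = probability_weight(p, params.gamma) * v**params.alpha
        eu_s = s**params.alpha  # certain option: pi(1) = 1
    else:  # pragma: no cover
        raise ValueError(f"unknown model {model!r}")
    return eu_s - eu_r


def signed_utility_gap(records: Sequence[ChoiceRecord], model: Model, params) -> np.ndarray:
    """Per-trial EU_safe - EU_risky under the given model (risky = assigned to self)."""
    p, v, s, _ = _trial_arrays(records)
    return _gap_arrays(p, v, s, model, params)


def log_likelihood(records: Sequence[ChoiceRecord], model: Model | str, params) -> float:
    """Summed log probability of the observed choices under ``model``.

    Always <= 0; with beta = 0 it equals n * ln(1/2) (the chance model).
    """
    if not records:
        raise ValueError("records is empty")
    model = Model(model)
    gap = signed_utility_gap(records, model, params)
    _, _, _, y = _trial_arrays(records)
    return float(np.sum(_log_p_choice(params.beta * gap, y)))


def simulate_choices(params, model: Model | str, choice_set: ChoiceSet, seed: int) -> list[ChoiceRecord]:
    """Draw one Bernoulli choice per trial from the model's choice probabilities."""
    model = Model(model)
    rng = np.random.default_rng(seed)
    shells = [ChoiceRecord(trial=t, chose_risky=False) for t in choice_set.trials]
    gap = signed_utility_gap(shells, model, params)
    p_risky = np.exp(-np.logaddexp(0.0, params.beta * gap))
    draws = rng.random(len(shells)) < p_risky
    return [ChoiceRecord(trial=t, chose_risky=bool(d)) for t, d in zip(choice_set.trials, draws)]
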