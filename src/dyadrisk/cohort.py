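"""Synthetic dyad cohorts with the statistical structure the analysis assumes.

The generator emulates a dyadic risky-choice study: friend pairs matched on
age (within 1.39 years), ages spanning 12.0-22.8 years, a risk-averse
population (alpha centred on 0.55, SD 0.23), a friend-outcome weight that
declines linearly with age, and a shift toward risk acceptance in the
Opposite context that is strongest in early adolescence: +0.35 on alpha at
age 12, declining linearly to zero by age 19. Averaged over the cohort this
taper contributes about +0.11 — the context's overall mean effect — while
only its early-adolescent portion is large enough to clear a simultaneous
95% band, confining the detectable context difference to the youngest ages.

Each agent contributes eight 35-trial blocks: Baseline, Identical, Opposite,
the four Observed/Unobserved Part-2 conditions, and a PredictedFriend block
(the agent's trial-by-trial predictions of their friend's baseline choices,
simulated from the agent's belief about the friend's exponent). Opposite-
family choices come from the social model using the agent's true weight and
belief exponent; all other blocks come from the two-parameter model with
per-condition alpha shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Model, OriginalParams, SocialParams, simulate_choices
from .task import OPPOSITE_FAMILY, Condition, build_choice_set

#: fitting box for the risk exponent; truths are kept inside it
_ALPHA_TRUNC = (0.05, 2.0)


def default_condition_shifts() -> dict[Condition, float]:
    """Additive alpha shifts per condition relative to an agent's baseline.

    Identical-family shifts are small constants (+0.04, with an extra +0.10
    under observation); Opposite-family shifts are age-dependent and handled
    separately (see ``opposite_alpha_shift``).
    """
    return {
        Condition.BASELINE: 0.0,
        Condition.IDENTICAL: 0.04,
        Condition.UNOBSERVED_IDENTICAL: 0.04,
        Condition.OBSERVED_IDENTICAL: 0.14,
        Condition.OPPOSITE: 0.0,
        Condition.UNOBSERVED_OPPOSITE: 0.0,
        Condition.OBSERVED_OPPOSITE: 0.0,
        Condition.PREDICTED_FRIEND: 0.0,
    }


@dataclass
class CohortConfig:
    """Generative settings; defaults reproduce the study-level structure."""

    n_dyads: int = 64
    age_range: tuple[float, float] = (12.0, 22.8)
    max_age_gap: float = 1.39
    alpha_mean: float = 0.55
    alpha_sd: float = 0.23
    w_intercept: float = 0.80
    w_age_slope: float = -0.025
    w_noise_sd: float = 0.12
    opposite_shift_all: float = 0.0
    opposite_shift_young: float = 0.35
    opposite_shift_end_age: float = 19.0
    beta_log_mean: float = float(np.log(3.0))
    beta_log_sd: float = 0.5
    belief_noise_sd: float = 0.1
    seed: int = 0
    condition_alpha_shifts: dict[Condition, float] = field(default_factory=default_condition_shifts)

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.alpha_sd <= 0 or self.beta_log_sd <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass
class SyntheticAgent:
    participant_id: str
    dyad_id: str
    age: float
    true_alpha_baseline: float
    true_beta: float
    true_w: float
    true_alpha_friend_belief: float
    condition_alpha_shifts: dict[Condition, float] = field(default_factory=dict)

    def alpha_for(self, condition: Condition, opposite_shift: float = 0.0) -> float:
        """Generative alpha in a condition, clamped to the identifiable box."""
        shift = self.condition_alpha_shifts.get(condition, 0.0)
        if condition in OPPOSITE_FAMILY:
            shift += opposite_shift
        return float(np.clip(self.true_alpha_baseline + shift, *_ALPHA_TRUNC))


def opposite_alpha_shift(age: float, config: CohortConfig) -> float:
    """Risk-acceptance shift in the Opposite context at a given age.

    A constant ``opposite_shift_all`` (zero by default) plus
    ``opposite_shift_young`` at the bottom of the age range, tapering
    linearly to zero by ``opposite_shift_end_age``. The default taper is
    calibrated so its cohort average matches the context's overall mean
    effect while staying concentrated at the youngest ages.
    """
    a0, a1 = config.age_range[0], config.opposite_shift_end_age
    frac = max(0.0, (a1 - age) / (a1 - a0))
    return config.opposite_shift_all + config.opposite_shift_young * min(1.0, frac)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[(draw > lo) & (draw < hi)][: size - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(config: CohortConfig | None = None) -> list[SyntheticAgent]:
    """Draw dyad-paired agents with ages, exponents, weights, and beliefs."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_dyads
    lo, hi = config.age_range

    # one anchor age per dyad; the partner sits within the allowed gap
    anchors = rng.uniform(lo, hi, size=config.n_dyads)
    gaps = rng.uniform(-config.max_age_gap, config.max_age_gap, size=config.n_dyads)
    partners = np.clip(anchors + gaps, lo, hi)
    ages = np.column_stack([anchors, partners]).ravel()

    alphas = _truncated_normal(rng, config.alpha_mean, config.alpha_sd, *_ALPHA_TRUNC, size=n)
    betas = rng.lognormal(config.beta_log_mean, config.beta_log_sd, size=n)
    w = np.clip(
        config.w_intercept + config.w_age_slope * ages + rng.normal(0.0, config.w_noise_sd, size=n),
        0.0,
        1.0,
    )

    agents: list[SyntheticAgent] = []
    for i in range(n):
        dyad = i // 2
        friend = i + 1 if i % 2 == 0 else i - 1
        belief = float(
            np.clip(alphas[friend] + rng.normal(0.0, config.belief_noise_sd), *_ALPHA_TRUNC)
        )
        agents.append(
            SyntheticAgent(
                participant_id=f"p{i:03d}",
                dyad_id=f"d{dyad:03d}",
                age=float(ages[i]),
                true_alpha_baseline=float(alphas[i]),
                true_beta=float(betas[i]),
                true_w=float(w[i]),
                true_alpha_friend_belief=belief,
                condition_alpha_shifts=dict(config.condition_alpha_shifts),
            )
        )
    return agents


def generate_study_dataset(
    cohort: list[SyntheticAgent],
    seed: int = 0,
    config: CohortConfig | None = None,
    conditions: list[Condition] | None = None,
) -> pd.DataFrame:
    """Simulate the full long-format trial table for every agent.

    One 35-trial block per agent per condition; Opposite-family blocks use the
    social model with the agent's true weight and belief exponent, everything
    else the two-parameter model. The PredictedFriend block simulates the
    agent's predictions of the friend's baseline choices from the belief
    exponent. Deterministic given ``seed``.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    config = config or CohortConfig()
    conditions = conditions or list(Condition)
    rng = np.random.default_rng(seed)
    frames = []
    for agent in cohort:
        for condition in conditions:
            set_seed = int(rng.integers(0, 2**31 - 1))
            sim_seed = int(rng.integers(0, 2**31 - 1))
            cset = build_choice_set(condition, seed=set_seed)
            if condition in OPPOSITE_FAMILY:
                shift = opposite_alpha_shift(agent.age, config)
                params = SocialParams(
                    alpha=agent.alpha_for(condition, opposite_shift=shift),
                    beta=agent.true_beta,
                    w=agent.true_w,
                    alpha_friend=agent.true_alpha_friend_belief,
                )
                records = simulate_choices(params, Model.REVISED, cset, seed=sim_seed)
            else:
                alpha = (
                    agent.true_alpha_friend_belief
                    if condition is Condition.PREDICTED_FRIEND
                    else agent.alpha_for(condition)
                )
                params = OriginalParams(alpha=alpha, beta=agent.true_beta)
                records = simulate_choices(params, Model.ORIGINAL, cset, seed=sim_seed)
            frame = cset.to_frame()
            frame.insert(0, "participant_id", agent.participant_id)
            frame.insert(1, "dyad_id", agent.dyad_id)
            frame.insert(2, "age", agent.age)
            frame["chose_risky"] = [r.chose_risky for r in records]
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def cohort_truth_frame(cohort: list[SyntheticAgent]) -> pd.DataFrame:
    """Ground-truth parameters per agent, for recovery scoring."""
    return pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in cohort],
            "dyad_id": [a.dyad_id for a in cohort],
            "age": [a.age for a in cohort],
            "true_alpha_baseline": [a.true_alpha_baseline for a in cohort],
            "true_beta": [a.true_beta for a in cohort],
            "true_w": [a.true_w for a in cohort],
            "true_alpha_friend_belief": [a.true_alpha_friend_belief for a in cohort],
        }
    )
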