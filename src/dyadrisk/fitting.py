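"""Per-participant maximum-likelihood fitting, AIC, and model-based exclusions.

Fits are per participant x condition, never hierarchical, so that no age
structure is imposed before the age-trend stage. The likelihood surface in
(alpha, beta) is multimodal at low beta, so every fit runs a multi-start grid
refined by bounded quasi-Newton (L-BFGS-B) and keeps the best start.

Exclusion rules mirror the task's identifiability analysis: exponents above
the set's maximum indifference alpha (3.32) are indistinguishable, Opposite
fits are restricted to the well-recovered alpha range [0, 2] and to weights
meaningfully above zero, and any fit no better than coin-flipping (AIC >=
chance AIC) is dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .models import ChoiceRecord, Model, _trial_arrays
from .task import BASELINE_FAMILY, OPPOSITE_FAMILY, Condition

ALPHA_BOUNDS = (0.01, 5.0)
BETA_BOUNDS = (0.001, 50.0)
W_BOUNDS = (0.0, 1.0)
GAMMA_BOUNDS = (0.05, 1.5)

ALPHA_STARTS = (0.2, 0.55, 1.0, 1.8)
BETA_STARTS = (0.5, 2.0, 8.0)
W_STARTS = (0.1, 0.35, 0.7)
GAMMA_STARTS = (0.5, 1.0)

MIN_RECORDS = 10
#: tolerance for counting two starts as having reached the same optimum
_AGREE_TOL = 0.01
#: log-likelihood differences below this are treated as ties when resolving
#: degenerate boundary solutions
_TIE_TOL = 0.01
#: an estimate this close to a box edge is flagged as a boundary solution
_BOUNDARY_EPS = 1e-6


class ExclusionReason(str, enum.Enum):
    ALPHA_BOUND = "alpha_bound"
    W_BOUND = "w_bound"
    AIC_CHANCE = "aic_chance"


@dataclass
class FitResult:
    """One participant x condition maximum-likelihood fit."""

    participant_id: str
    condition: Condition
    model: Model
    estimates: dict[str, float]
    loglik: float
    k: int
    n_trials: int
    converged: bool
    n_starts_agreeing: int
    at_boundary: bool = False
    dyad_id: str | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass
class ExclusionConfig:
    """Thresholds of the model-based exclusion rules (defaults as published)."""

    alpha_max_baseline_identical: float = 3.32
    alpha_max_opposite: float = 2.0
    w_min: float = 1e-6
    aic_vs_chance: bool = True
    enabled: bool = True  # False reproduces full-sample sensitivity analyses

    def __post_init__(self) -> None:
        if min(self.alpha_max_baseline_identical, self.alpha_max_opposite, self.w_min) <= 0:
            raise ValueError("all exclusion thresholds must be positive")


@dataclass
class ExclusionFlag:
    participant_id: str
    condition: Condition
    excluded: bool
    reasons: list[ExclusionReason] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must hold exactly when reasons is non-empty")


def chance_aic(n_trials: int, k: int) -> float:
    """AIC of a coin-flipping chooser: 2k - 2 n ln(1/2)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return 2.0 * k - 2.0 * n_trials * np.log(0.5)


def _at_bounds(x: np.ndarray, bounds: Sequence[tuple[float, float]]) -> bool:
    return any(
        xi <= lo + _BOUNDARY_EPS * max(1.0, abs(lo)) or xi >= hi - _BOUNDARY_EPS * max(1.0, abs(hi))
        for xi, (lo, hi) in zip(x, bounds)
    )


def _multistart_mle(records, starts, bounds, gap_beta, interior_dims=()):
    """Maximize the likelihood from every start; return best x, loglik, diagnostics.

    ``gap_beta(x, p, v, s)`` returns the per-trial EU_safe - EU_risky and the
    inverse noise for parameter vector x; the logistic log-likelihood is
    evaluated directly on pre-extracted arrays.

    Starts whose log-likelihoods tie to within ``_TIE_TOL`` are statistically
    indistinguishable; among them, solutions interior in the dimensions
    listed in ``interior_dims`` are preferred over boundary ones — a
    parameter pinned at its box edge in a likelihood tie is a degenerate
    report, not evidence. Used for the social model's weight, which sits on a
    flat (w, beta) ridge whenever a participant's exponent is close to their
    believed friend exponent. A boundary solution that is strictly better
    than every interior one is kept.
    """
    p, v, s, y = _trial_arrays(records)

    def nll(x: np.ndarray) -> float:
        gap, beta = gap_beta(x, p, v, s)
        arg = beta * gap
        logp = np.where(y, -np.logaddexp(0.0, arg), -np.logaddexp(0.0, -arg))
        return -float(np.sum(logp))

    results = []
    for x0 in starts:
        res = minimize(nll, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds)
        results.append(res)
    best_fun = min(r.fun for r in results)
    n_agree = sum(1 for r in results if np.isfinite(r.fun) and r.fun - best_fun <= _AGREE_TOL)
    tied = [r for r in results if np.isfinite(r.fun) and r.fun - best_fun <= _TIE_TOL]
    interior = [
        r
        for r in tied
        if not _at_bounds(r.x[list(interior_dims)], [bounds[i] for i in interior_dims])
    ]
    pick = min(interior or tied, key=lambda r: r.fun)
    converged = any(r.success for r in results)
    return pick.x, -float(pick.fun), converged, n_agree


def fit_original(
    records: Sequence[ChoiceRecord],
    participant_id: str = "",
    condition: Condition = Condition.BASELINE,
    dyad_id: str | None = None,
) -> FitResult:
    """Fit the two-parameter expected-utility model (alpha, beta) by MLE."""
    if len(records) < MIN_RECORDS:
        raise ValueError(f"need at least {MIN_RECORDS} records, got {len(records)}")
    bounds = [ALPHA_BOUNDS, BETA_BOUNDS]
    starts = [(a, b) for a in ALPHA_STARTS for b in BETA_STARTS]
    gap_beta = lambda x, p, v, s: (s ** x[0] - p * v ** x[0], x[1])
    x, ll, conv, n_agree = _multistart_mle(records, starts, bounds, gap_beta)
    return FitResult(
        participant_id=participant_id,
        condition=condition,
        model=Model.ORIGINAL,
        estimates={"alpha": float(x[0]), "beta": float(x[1])},
        loglik=ll,
        k=2,
        n_trials=len(records),
        converged=conv,
        n_starts_agreeing=n_agree,
        at_boundary=_at_bounds(x, bounds),
        dyad_id=dyad_id,
    )


def fit_revised(
    records: Sequence[ChoiceRecord],
    alpha_friend: float,
    participant_id: str = "",
    condition: Condition = Condition.OPPOSITE,
    dyad_id: str | None = None,
    alpha_max: float = ALPHA_BOUNDS[1],
) -> FitResult:
    """Fit the social model (alpha, beta, w) with alpha_friend held fixed.

    ``alpha_max`` optionally narrows the exponent's box (recovery harnesses
    restrict it to the identifiable range [0, 2]).
    """
    if len(records) < MIN_RECORDS:
        raise ValueError(f"need at least {MIN_RECORDS} records, got {len(records)}")
    if not np.isfinite(alpha_friend) or alpha_friend <= 0:
        raise ValueError(f"alpha_friend must be finite and positive, got {alpha_friend}")
    bounds = [(ALPHA_BOUNDS[0], alpha_max), BETA_BOUNDS, W_BOUNDS]
    starts = [(a, b, w) for a in ALPHA_STARTS if a < alpha_max for b in BETA_STARTS for w in W_STARTS]

    def gap_beta(x, p, v, s):
        a, beta, w = x
        eu_r = (1.0 - w) * p * v**a + w * s**alpha_friend
        eu_s = (1.0 - w) * s**a + w * p * v**alpha_friend
        return eu_s - eu_r, beta

    # dimension 2 is w: prefer ridge-free interior weights among likelihood ties
    x, ll, conv, n_agree = _multistart_mle(records, starts, bounds, gap_beta, interior_dims=(2,))
    return FitResult(
        participant_id=participant_id,
        condition=condition,
        model=Model.REVISED,
        estimates={"alpha": float(x[0]), "beta": float(x[1]), "w": float(x[2]), "alpha_friend": float(alpha_friend)},
        loglik=ll,
        k=3,
        n_trials=len(records),
        converged=conv,
        n_starts_agreeing=n_agree,
        at_boundary=_at_bounds(x, bounds),
        dyad_id=dyad_id,
    )


def fit_prospect(
    records: Sequence[ChoiceRecord],
    participant_id: str = "",
    condition: Condition = Condition.BASELINE,
    dyad_id: str | None = None,
) -> FitResult:
    """Fit the gains-only prospect-theory alternative (alpha, gamma, beta)."""
    if len(records) < MIN_RECORDS:
        raise ValueError(f"need at least {MIN_RECORDS} records, got {len(records)}")
    bounds = [ALPHA_BOUNDS, GAMMA_BOUNDS, BETA_BOUNDS]
    starts = [(a, g, b) for a in ALPHA_STARTS for g in GAMMA_STARTS for b in BETA_STARTS]

    def gap_beta(x, p, v, s):
        a, g, beta = x
        pi = p**g / (p**g + (1.0 - p) ** g) ** (1.0 / g)
        return s**a - pi * v**a, beta

    x, ll, conv, n_agree = _multistart_mle(records, starts, bounds, gap_beta)
    return FitResult(
        participant_id=participant_id,
        condition=condition,
        model=Model.PROSPECT,
        estimates={"alpha": float(x[0]), "gamma": float(x[1]), "beta": float(x[2])},
        loglik=ll,
        k=3,
        n_trials=len(records),
        converged=conv,
        n_starts_agreeing=n_agree,
        at_boundary=_at_bounds(x, bounds),
        dyad_id=dyad_id,
    )


def estimate_alpha_friend(predicted_friend_records: Sequence[ChoiceRecord], participant_id: str = "") -> float:
    """Believed friend risk exponent: alpha of the original model fit to the
    participant's trial-by-trial predictions of their friend's baseline choices."""
    fit = fit_original(predicted_friend_records, participant_id=participant_id, condition=Condition.PREDICTED_FRIEND)
    return fit.estimates["alpha"]


def apply_exclusions(fits: Sequence[FitResult], config: ExclusionConfig | None = None) -> list[ExclusionFlag]:
    """Flag fits that fail the identifiability or chance-behaviour rules.

    Baseline/Identical-family fits are excluded when alpha exceeds the set's
    maximum recoverable value; Opposite-family fits when alpha exceeds 2 or
    the friend weight is below 1e-6; any fit when its AIC is at or above the
    chance AIC for the same trial count and parameter count. Exclusions are
    per condition; with ``config.enabled = False`` every fit is kept
    (full-sample sensitivity mode).
    """
    config = config or ExclusionConfig()
    flags = []
    for fit in fits:
        reasons: list[ExclusionReason] = []
        if config.enabled:
            alpha = fit.estimates.get("alpha", np.nan)
            if fit.condition in OPPOSITE_FAMILY:
                if alpha > config.alpha_max_opposite:
                    reasons.append(ExclusionReason.ALPHA_BOUND)
                if fit.estimates.get("w", np.inf) < config.w_min:
                    reasons.append(ExclusionReason.W_BOUND)
            elif fit.condition in BASELINE_FAMILY:
                if alpha > config.alpha_max_baseline_identical:
                    reasons.append(ExclusionReason.ALPHA_BOUND)
            else:
                raise ValueError(f"unknown condition family for {fit.condition!r}")
            if config.aic_vs_chance and fit.aic >= chance_aic(fit.n_trials, fit.k):
                reasons.append(ExclusionReason.AIC_CHANCE)
        flags.append(
            ExclusionFlag(
                participant_id=fit.participant_id,
                condition=fit.condition,
                excluded=bool(reasons),
                reasons=reasons,
            )
        )
    return flags


def fits_to_frame(fits: Sequence[FitResult], flags: Sequence[ExclusionFlag] | None = None):
    """Serialize fits (and optional flags) to a long DataFrame."""
    import pandas as pd

    flag_map = {}
    if flags is not None:
        flag_map = {(f.participant_id, f.condition): f for f in flags}
    rows = []
    for fit in fits:
        flag = flag_map.get((fit.participant_id, fit.condition))
        rows.append(
            {
                "participant_id": fit.participant_id,
                "dyad_id": fit.dyad_id,
                "condition": fit.condition.value,
                "model": fit.model.value,
                "alpha": fit.estimates.get("alpha"),
                "beta": fit.estimates.get("beta"),
                "w": fit.estimates.get("w"),
                "alpha_friend": fit.estimates.get("alpha_friend"),
                "gamma": fit.estimates.get("gamma"),
                "loglik": fit.loglik,
                "k": fit.k,
                "aic": fit.aic,
                "converged": fit.converged,
                "at_boundary": fit.at_boundary,
                "excluded": flag.excluded if flag else None,
                "reasons": ";".join(r.value for r in flag.reasons) if flag else None,
            }
        )
    return pd.DataFrame(rows)
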