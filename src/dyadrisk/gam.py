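"""Nonlinear age-trend inference with penalized-spline additive models.

The age analyses ask where, along a continuous age axis, a dependent variable
(fitted risk exponent, friend weight, or earnings proportion) changes or
differs between conditions — without assuming a functional form. The model is

    dv ~ condition + f_condition(age) + (1 | dyad) + (1 | participant:dyad)

with one penalized cubic B-spline smooth per condition level (a factor-smooth
interaction, each with its own smoothing parameter) and random intercepts for
dyads and for participants nested within dyads, implemented as ridge-penalized
dummy blocks. Gaussian smoothing parameters are selected by restricted
maximum likelihood (REML); earnings proportions use a Beta family with logit
link (see :func:`fit_proportion_model`).

Inference on "where" uses the Bayesian view of the penalized fit: coefficient
vectors are drawn from N(beta_hat, V_beta), the maximum standardized absolute
deviation over the evaluation grid gives a simultaneous critical value, and
pointwise intervals widened by it form a 95% simultaneous band. Age windows
where the band around the first derivative (or around a between-condition
difference of fit estimates) excludes zero mark significant change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, expit, logit, polygamma

DEFAULT_BASIS_DIM = 10
DEFAULT_N_POINTS = 100
DEFAULT_N_DRAWS = 10_000
_DEGREE = 3
_LOG_LAMBDA_BOUNDS = (-12.0, 14.0)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    """One coefficient block of the design: columns, penalty, its REML bookkeeping."""

    name: str
    sl: slice
    penalty: np.ndarray | None  # unit penalty on the block's own columns
    rank: int = 0
    null_dim: int = 0
    is_smooth: bool = False
    condition: str | None = None


@dataclass
class DesignInfo:
    """Everything needed to rebuild design rows for new ages/conditions."""

    knots: np.ndarray
    basis_dim: int
    age_range: tuple[float, float]
    levels: list[str]
    terms: list[_Term]
    n_cols: int
    smooth_Z: dict[str, np.ndarray]  # per-condition centering reparameterization
    dyad_levels: list[str] = field(default_factory=list)
    participant_levels: list[str] = field(default_factory=list)

    def _raw_basis(self, ages: np.ndarray) -> np.ndarray:
        lo, hi = self.age_range
        a = np.clip(np.asarray(ages, dtype=float), lo, hi)
        return BSpline.design_matrix(a, self.knots, _DEGREE).toarray()

    def population_design(self, ages: np.ndarray, condition: str | None) -> np.ndarray:
        """Design rows at the population level (random-effect columns zero)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        X = np.zeros((ages.size, self.n_cols))
        raw = self._raw_basis(ages)
        for term in self.terms:
            if term.name == "intercept":
                X[:, term.sl] = 1.0
            elif term.name.startswith("condition:"):
                lev = term.name.split(":", 1)[1]
                if condition is not None and lev == condition:
                    X[:, term.sl] = 1.0
            elif term.is_smooth and term.condition is not None:
                if condition is not None and term.condition == condition:
                    X[:, term.sl] = raw @ self.smooth_Z[term.condition]
            elif term.is_smooth:  # single shared smooth
                X[:, term.sl] = raw @ self.smooth_Z["__all__"]
        return X


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _centering_transform(basis_active: np.ndarray) -> np.ndarray:
    """Null space of the sum-to-zero constraint over the active rows."""
    c = basis_active.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(c)
    return vt[1:].T  # k x (k-1)


def _penalty_rank(S: np.ndarray) -> tuple[int, int]:
    ev = np.linalg.eigvalsh(S)
    tol = max(S.shape) * np.max(np.abs(ev)) * 1e-10
    rank = int(np.sum(ev > tol))
    return rank, S.shape[0] - rank


def _logdet_plus(S: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(S)
    tol = max(S.shape) * np.max(np.abs(ev)) * 1e-10
    return float(np.sum(np.log(ev[ev > tol])))


def _build_design(
    table: pd.DataFrame,
    dv: str,
    age_col: str,
    condition_col: str | None,
    participant_col: str | None,
    dyad_col: str | None,
    basis_dim: int,
) -> tuple[np.ndarray, np.ndarray, DesignInfo]:
    ages = table[age_col].to_numpy(dtype=float)
    y = table[dv].to_numpy(dtype=float)
    n = len(table)
    distinct = np.unique(ages)
    if distinct.size < basis_dim:
        raise ValueError(
            f"only {distinct.size} distinct ages but the spline basis needs at least "
            f"{basis_dim}; lower basis_dim or supply more spread in age"
        )
    lo, hi = float(distinct.min()), float(distinct.max())
    interior = np.quantile(distinct, np.linspace(0, 1, basis_dim - _DEGREE + 1)[1:-1])
    knots = np.concatenate([[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)])

    raw = BSpline.design_matrix(ages, knots, _DEGREE).toarray()
    S_raw = _difference_penalty(basis_dim)

    levels: list[str] = []
    if condition_col is not None and condition_col in table.columns:
        seen = table[condition_col].astype(str)
        levels = list(dict.fromkeys(seen))
        if len(levels) < 2:
            levels = levels  # single level: no dummies, one smooth
    blocks: list[np.ndarray] = []
    terms: list[_Term] = []
    smooth_Z: dict[str, np.ndarray] = {}
    col = 0

    def add(name: str, X: np.ndarray, penalty=None, is_smooth=False, condition=None):
        nonlocal col
        sl = slice(col, col + X.shape[1])
        blocks.append(X)
        t = _Term(name=name, sl=sl, penalty=penalty, is_smooth=is_smooth, condition=condition)
        if penalty is not None:
            t.rank, t.null_dim = _penalty_rank(penalty)
        else:
            t.null_dim = X.shape[1]
        terms.append(t)
        col += X.shape[1]

    add("intercept", np.ones((n, 1)))

    if len(levels) >= 2:
        cond = table[condition_col].astype(str).to_numpy()
        for lev in levels[1:]:
            add(f"condition:{lev}", (cond == lev).astype(float)[:, None])
        for lev in levels:
            active = cond == lev
            Z = _centering_transform(raw[active])
            smooth_Z[lev] = Z
            Xs = np.where(active[:, None], raw @ Z, 0.0)
            add(f"s(age):{lev}", Xs, penalty=Z.T @ S_raw @ Z, is_smooth=True, condition=lev)
    else:
        Z = _centering_transform(raw)
        smooth_Z["__all__"] = Z
        add("s(age)", raw @ Z, penalty=Z.T @ S_raw @ Z, is_smooth=True)

    dyad_levels: list[str] = []
    participant_levels: list[str] = []
    if dyad_col is not None and dyad_col in table.columns and table[dyad_col].nunique() > 1:
        dyad_levels = sorted(table[dyad_col].astype(str).unique())
        d = pd.get_dummies(pd.Categorical(table[dyad_col].astype(str), categories=dyad_levels))
        add("re(dyad)", d.to_numpy(dtype=float), penalty=np.eye(len(dyad_levels)))
    if (
        participant_col is not None
        and participant_col in table.columns
        and table[participant_col].duplicated().any()
    ):
        participant_levels = sorted(table[participant_col].astype(str).unique())
        d = pd.get_dummies(pd.Categorical(table[participant_col].astype(str), categories=participant_levels))
        add("re(participant)", d.to_numpy(dtype=float), penalty=np.eye(len(participant_levels)))

    X = np.hstack(blocks)
    info = DesignInfo(
        knots=knots,
        basis_dim=basis_dim,
        age_range=(lo, hi),
        levels=levels,
        terms=terms,
        n_cols=X.shape[1],
        smooth_Z=smooth_Z,
        dyad_levels=dyad_levels,
        participant_levels=participant_levels,
    )
    return X, y, info


def _assemble_penalty(info: DesignInfo, log_lambdas: np.ndarray) -> np.ndarray:
    S = np.zeros((info.n_cols, info.n_cols))
    j = 0
    for term in info.terms:
        if term.penalty is None:
            continue
        S[term.sl, term.sl] += np.exp(log_lambdas[j]) * term.penalty
        j += 1
    return S


def _penalized_terms(info: DesignInfo) -> list[_Term]:
    return [t for t in info.terms if t.penalty is not None]


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------


@dataclass
class SmoothFit:
    """A fitted additive age model with its coefficient posterior."""

    dv: str
    family: str
    design: DesignInfo
    beta: np.ndarray
    cov: np.ndarray  # posterior covariance of beta
    scale: float  # sigma^2 (gaussian) or 1/(1+phi)-style dispersion echo (beta)
    edf_total: float
    edf_by_term: dict[str, float]
    lambdas: dict[str, float]
    parametric: pd.DataFrame  # term, estimate, se, stat, p
    smooth_stats: pd.DataFrame  # term, edf
    n: int
    phi: float | None = None
    boundary_squeezed: bool = False

    def predict(self, ages, condition: str | None = None, link_scale: bool = True) -> np.ndarray:
        """Population-level fitted values at given ages for one condition."""
        X = self.design.population_design(np.asarray(ages, dtype=float), condition)
        eta = X @ self.beta
        if self.family == "beta" and not link_scale:
            return expit(eta)
        return eta

    @property
    def age_grid(self) -> np.ndarray:
        lo, hi = self.design.age_range
        return np.linspace(lo, hi, DEFAULT_N_POINTS)


@dataclass
class DerivativeBand:
    """First derivative of the age smooth with a simultaneous confidence band."""

    ages: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    se: np.ndarray
    crit: float
    level: float = 0.95
    condition: str | None = None

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.estimate + 1e-12) and np.all(self.estimate <= self.upper + 1e-12)):
            raise ValueError("band must bracket the estimate at every point")

    def excludes_zero(self) -> np.ndarray:
        return (self.lower > 0) | (self.upper < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "excludes_zero": self.excludes_zero(),
            }
        )


@dataclass
class DifferenceBand:
    """Difference of fit estimates between two conditions with simultaneous band."""

    condition_a: str
    condition_b: str
    ages: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    se: np.ndarray
    crit: float
    level: float = 0.95

    def excludes_zero(self) -> np.ndarray:
        return (self.lower > 0) | (self.upper < 0)

    @property
    def significant_intervals(self) -> list[tuple[float, float]]:
        return _runs_to_intervals(self.ages, self.excludes_zero())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "excludes_zero": self.excludes_zero(),
            }
        )


# ---------------------------------------------------------------------------
# Gaussian REML fit
# ---------------------------------------------------------------------------


def _gaussian_reml_fit(X: np.ndarray, y: np.ndarray, info: DesignInfo):
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    pen_terms = _penalized_terms(info)
    n_pen = len(pen_terms)
    m_null = sum(t.null_dim for t in info.terms)
    logdet_units = [_logdet_plus(t.penalty) for t in pen_terms]

    def criterion(log_lam: np.ndarray) -> float:
        log_lam = np.clip(log_lam, *_LOG_LAMBDA_BOUNDS)
        S = _assemble_penalty(info, log_lam)
        H = XtX + S
        try:
            L = np.linalg.cholesky(H + 1e-10 * np.eye(p))
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(H + 1e-10 * np.eye(p), Xty)
        P = max(yty - beta @ Xty, 1e-300)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_S = sum(
            t.rank * ll + ld for t, ll, ld in zip(pen_terms, log_lam, logdet_units)
        )
        return (n - m_null) * np.log(P) + logdet_H - logdet_S

    if n_pen:
        x0 = np.zeros(n_pen)
        res = minimize(criterion, x0, method="Nelder-Mead", options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 4000})
        log_lam = np.clip(res.x, *_LOG_LAMBDA_BOUNDS)
    else:
        log_lam = np.zeros(0)

    S = _assemble_penalty(info, log_lam)
    H = XtX + S + 1e-10 * np.eye(p)
    Hinv = np.linalg.inv(H)
    beta = Hinv @ Xty
    P = max(yty - beta @ Xty, 1e-300)
    sigma2 = P / (n - m_null)
    cov = sigma2 * Hinv
    A = Hinv @ XtX
    edf_cols = np.diag(A)
    return beta, cov, sigma2, edf_cols, log_lam


# ---------------------------------------------------------------------------
# Beta-family penalized fit (logit link)
# ---------------------------------------------------------------------------


def _beta_penalized_fit(X: np.ndarray, y: np.ndarray, S: np.ndarray, beta0: np.ndarray):
    """Penalized ML for a Beta GLM: Fisher scoring in beta, 1-D search in phi."""
    beta = beta0.copy()
    phi = 10.0

    def mu_of(b):
        return np.clip(expit(X @ b), 1e-6, 1 - 1e-6)

    def nll(b, ph):
        mu = mu_of(b)
        a, c = mu * ph, (1 - mu) * ph
        ll = (
            stats.beta.logpdf(y, a, c).sum()
        )
        return -(ll - 0.5 * b @ S @ b)

    for _ in range(60):
        mu = mu_of(beta)
        a, c = mu * phi, (1 - mu) * phi
        ystar = np.log(y) - np.log1p(-y)
        mustar = digamma(a) - digamma(c)
        dmu = mu * (1 - mu)
        score_eta = phi * (ystar - mustar) * dmu
        w = phi**2 * (polygamma(1, a) + polygamma(1, c)) * dmu**2
        Hp = X.T @ (w[:, None] * X) + S
        step = np.linalg.solve(Hp + 1e-10 * np.eye(X.shape[1]), X.T @ score_eta - S @ beta)
        # halving line search on the penalized objective
        f0 = nll(beta, phi)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            if nll(cand, phi) < f0 + 1e-12:
                break
            t *= 0.5
        new_beta = beta + t * step
        moved = np.max(np.abs(new_beta - beta))
        beta = new_beta
        res = minimize_scalar(lambda lp: nll(beta, np.exp(lp)), bounds=(-2, 12), method="bounded")
        phi_new = float(np.exp(res.x))
        if moved < 1e-8 and abs(np.log(phi_new) - np.log(phi)) < 1e-8:
            phi = phi_new
            break
        phi = phi_new

    mu = mu_of(beta)
    a, c = mu * phi, (1 - mu) * phi
    dmu = mu * (1 - mu)
    w = phi**2 * (polygamma(1, a) + polygamma(1, c)) * dmu**2
    Hp = X.T @ (w[:, None] * X) + S + 1e-10 * np.eye(X.shape[1])
    cov = np.linalg.inv(Hp)
    edf_cols = np.diag(cov @ (X.T @ (w[:, None] * X)))
    return beta, cov, phi, edf_cols


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def fit_age_smooth(
    table: pd.DataFrame,
    dv: str,
    age_col: str = "age",
    condition_col: str | None = "condition",
    participant_col: str | None = "participant_id",
    dyad_col: str | None = "dyad_id",
    basis_dim: int = DEFAULT_BASIS_DIM,
    family: str = "gaussian",
) -> SmoothFit:
    """Fit dv ~ condition + f_condition(age) + dyad/participant random intercepts.

    Gaussian family for parameter DVs (risk exponent, friend weight); use
    :func:`fit_proportion_model` for earnings proportions. Smoothing
    parameters, including the random-intercept variances, are selected by
    REML. Parametric condition terms are reported with estimate, SE, t (or z)
    and p-value; smooths with their effective degrees of freedom.
    """
    if dv not in table.columns:
        raise ValueError(f"column {dv!r} not in table")
    table = table.dropna(subset=[dv]).reset_index(drop=True)
    X, y, info = _build_design(table, dv, age_col, condition_col, participant_col, dyad_col, basis_dim)

    squeezed = False
    if family == "beta":
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("beta family requires the dv to lie in [0, 1]")
        if np.any(y <= 0) or np.any(y >= 1):
            n = len(y)
            y = (y * (n - 1) + 0.5) / n
            squeezed = True

    # Gaussian REML provides the smoothing parameters (on the logit scale for beta)
    y_work = logit(np.clip(y, 1e-6, 1 - 1e-6)) if family == "beta" else y
    beta_hat, cov, sigma2, edf_cols, log_lam = _gaussian_reml_fit(X, y_work, info)
    phi = None
    if family == "beta":
        S = _assemble_penalty(info, log_lam)
        beta_hat, cov, phi, edf_cols = _beta_penalized_fit(X, y, S, beta_hat)
        sigma2 = 1.0 / (1.0 + phi)

    edf_by_term = {t.name: float(np.sum(edf_cols[t.sl])) for t in info.terms}
    edf_total = float(np.sum(edf_cols))

    rows = []
    df_resid = max(len(y) - edf_total, 1.0)
    for t in info.terms:
        if t.is_smooth or t.penalty is not None:
            continue
        for j in range(t.sl.start, t.sl.stop):
            est = float(beta_hat[j])
            se = float(np.sqrt(max(cov[j, j], 0.0)))
            stat = est / se if se > 0 else np.nan
            if family == "beta":
                pval = 2 * stats.norm.sf(abs(stat))
            else:
                pval = 2 * stats.t.sf(abs(stat), df_resid)
            rows.append(
                {
                    "term": t.name,
                    "estimate": est,
                    "se": se,
                    "z" if family == "beta" else "t": stat,
                    "p": float(pval),
                }
            )
    parametric = pd.DataFrame(rows)
    smooth_stats = pd.DataFrame(
        [{"term": t.name, "edf": edf_by_term[t.name]} for t in info.terms if t.is_smooth]
    )

    pen_terms = _penalized_terms(info)
    lambdas = {t.name: float(np.exp(l)) for t, l in zip(pen_terms, log_lam)}
    return SmoothFit(
        dv=dv,
        family=family,
        design=info,
        beta=beta_hat,
        cov=cov,
        scale=float(sigma2),
        edf_total=edf_total,
        edf_by_term=edf_by_term,
        lambdas=lambdas,
        parametric=parametric,
        smooth_stats=smooth_stats,
        n=len(y),
        phi=phi,
        boundary_squeezed=squeezed,
    )


def fit_proportion_model(
    table: pd.DataFrame,
    dv: str = "earnings_prop",
    **kwargs,
) -> SmoothFit:
    """Beta-family (logit link) age model for proportion outcomes.

    Proportions exactly at 0 or 1 are squeezed by (y (n-1) + 0.5) / n before
    fitting, recorded on the returned fit; parametric statistics are z-values.
    """
    return fit_age_smooth(table, dv, family="beta", **kwargs)


# ---------------------------------------------------------------------------
# simultaneous bands
# ---------------------------------------------------------------------------


def _simultaneous_crit(
    Xp: np.ndarray, cov: np.ndarray, se: np.ndarray, level: float, n_draws: int, seed: int
) -> float:
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.mean(np.diag(cov)) * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as err:
        raise ValueError("coefficient covariance is singular; cannot draw from posterior") from err
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, cov.shape[0])) @ L.T
    dev = np.abs(draws @ Xp.T) / se[None, :]
    return float(np.quantile(dev.max(axis=1), level))


def derivative_simultaneous_band(
    fit: SmoothFit,
    condition: str | None = None,
    n_points: int = DEFAULT_N_POINTS,
    n_draws: int = DEFAULT_N_DRAWS,
    level: float = 0.95,
    seed: int = 0,
) -> DerivativeBand:
    """First derivative of the fitted age curve with a simultaneous band.

    Central finite differences (step 1e-4 of the age range) of the
    population-level linear predictor, evaluated at ``n_points`` ages;
    the simultaneous critical value comes from ``n_draws`` posterior draws.
    """
    lo, hi = fit.design.age_range
    h = 1e-4 * (hi - lo)
    ages = np.linspace(lo + h, hi - h, n_points)
    Xp = (
        fit.design.population_design(ages + h, condition)
        - fit.design.population_design(ages - h, condition)
    ) / (2 * h)
    est = Xp @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xp, fit.cov, Xp), 1e-300))
    crit = _simultaneous_crit(Xp, fit.cov, se, level, n_draws, seed)
    return DerivativeBand(
        ages=ages,
        estimate=est,
        lower=est - crit * se,
        upper=est + crit * se,
        se=se,
        crit=crit,
        level=level,
        condition=condition,
    )


def difference_smooth(
    fit: SmoothFit,
    condition_a: str,
    condition_b: str,
    n_points: int = DEFAULT_N_POINTS,
    n_draws: int = DEFAULT_N_DRAWS,
    level: float = 0.95,
    seed: int = 0,
) -> DifferenceBand:
    """Difference of fit estimates (a minus b) across age, with simultaneous band.

    Includes the parametric condition offsets as well as the smooths, so it is
    the full population-level contrast between the two condition curves.
    """
    for c in (condition_a, condition_b):
        if c not in fit.design.levels:
            raise ValueError(f"condition {c!r} not among fitted levels {fit.design.levels}")
    lo, hi = fit.design.age_range
    ages = np.linspace(lo, hi, n_points)
    Xp = fit.design.population_design(ages, condition_a) - fit.design.population_design(ages, condition_b)
    est = Xp @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xp, fit.cov, Xp), 1e-300))
    crit = _simultaneous_crit(Xp, fit.cov, se, level, n_draws, seed)
    return DifferenceBand(
        condition_a=condition_a,
        condition_b=condition_b,
        ages=ages,
        estimate=est,
        lower=est - crit * se,
        upper=est + crit * se,
        se=se,
        crit=crit,
        level=level,
    )


def _runs_to_intervals(ages: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(ages[start]), float(ages[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(ages[start]), float(ages[-1])))
    return intervals


def significant_windows(band: DerivativeBand | DifferenceBand) -> list[tuple[float, float]]:
    """Maximal age intervals where the simultaneous band excludes zero."""
    return _runs_to_intervals(band.ages, band.excludes_zero())
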