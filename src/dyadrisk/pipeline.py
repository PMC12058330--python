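"""Orchestration and I/O: trial-table validation, per-stage runs, report bundle.

The full analysis mirrors four research questions:

1. Baseline age trend — does the risk exponent (and the earnings proportion)
   change with age absent friend involvement?
2. Friend-outcome contexts — do Identical and Opposite contexts shift risk
   preferences relative to Baseline, and where in the age range?
3. Observation — within each context, does being watched by the friend change
   behaviour (4-level condition factor; Identical and Opposite contexts are
   never contrasted directly)?
4. Friend weight — does the weight placed on the friend's outcome in the
   Opposite context change with age?

Each stage writes CSVs stamped with a hash of the generating configuration,
plus simple band figures and a text summary. A run is reproducible from the
config and global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import gam
from .cohort import CohortConfig, generate_cohort, generate_study_dataset, cohort_truth_frame
from .fitting import (
    ExclusionConfig,
    FitResult,
    apply_exclusions,
    estimate_alpha_friend,
    fit_original,
    fit_revised,
    fits_to_frame,
)
from .models import ChoiceRecord
from .task import (
    GRID_AMOUNTS,
    GRID_PROBABILITIES,
    OPPOSITE_FAMILY,
    ChoiceSet,
    ChoiceTrial,
    Condition,
    Lottery,
)

log = logging.getLogger("dyadrisk")

REQUIRED_COLUMNS = (
    "participant_id",
    "dyad_id",
    "age",
    "condition",
    "trial_index",
    "p_win",
    "amount",
    "safe_amount",
    "chose_risky",
)


@dataclass
class PipelineConfig:
    """Reproducible settings for a full analysis run."""

    input_path: str | None = None  # long trial CSV; None -> synthetic cohort
    cohort: CohortConfig = field(default_factory=CohortConfig)
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    seed: int = 0
    n_band_draws: int = gam.DEFAULT_N_DRAWS
    basis_dim: int = gam.DEFAULT_BASIS_DIM
    out_dir: str = "dyadrisk_out"
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["condition_alpha_shifts"] = {
            k.value: v for k, v in self.cohort.condition_alpha_shifts.items()
        }
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("make_figures", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_trial_table(path: str | Path, off_grid: str = "warn") -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Checks required columns, condition labels, probability grid membership
    (``off_grid`` one of 'warn', 'reject', 'accept'), and that every dyad has
    exactly two members. Raises descriptive errors naming the offending rows.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    valid_conditions = {c.value for c in Condition}
    bad = df.loc[~df["condition"].isin(valid_conditions)]
    if len(bad):
        raise ValueError(
            f"unknown condition label {bad['condition'].iloc[0]!r} at row {bad.index[0]}"
        )
    grid = set(GRID_PROBABILITIES)
    off = df.loc[~df["p_win"].round(6).isin({round(p, 6) for p in grid})]
    if len(off):
        msg = f"{len(off)} rows have off-grid p_win values (first at row {off.index[0]})"
        if off_grid == "reject":
            raise ValueError(msg)
        if off_grid == "warn":
            log.warning(msg)
    sizes = df.groupby("dyad_id")["participant_id"].nunique()
    orphans = sizes[sizes != 2]
    if len(orphans):
        raise ValueError(f"dyads without exactly two members: {list(orphans.index)}")
    df["chose_risky"] = df["chose_risky"].astype(bool)
    return df


def records_from_frame(group: pd.DataFrame) -> tuple[list[ChoiceRecord], ChoiceSet]:
    """Rebuild ChoiceRecords and their ChoiceSet from one participant-condition block."""
    group = group.sort_values("trial_index")
    condition = Condition(group["condition"].iloc[0])
    trials, records = [], []
    for _, row in group.iterrows():
        trial = ChoiceTrial(
            trial_index=int(row["trial_index"]),
            safe=Lottery(p_win=1.0, amount=float(row["safe_amount"])),
            risky=Lottery(p_win=float(row["p_win"]), amount=float(row["amount"])),
            risky_side=str(row.get("risky_side", "left")),
        )
        trials.append(trial)
        records.append(ChoiceRecord(trial=trial, chose_risky=bool(row["chose_risky"])))
    return records, ChoiceSet(condition=condition, trials=trials)


def fit_participants(table: pd.DataFrame) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit every participant x condition: two-parameter model for the
    Baseline/Identical family, social model (with the participant's own
    predicted-friend exponent) for the Opposite family. Also returns
    model-free behaviour summaries."""
    fits: list[FitResult] = []
    behavior_rows = []
    for pid, sub in table.groupby("participant_id", sort=True):
        dyad = str(sub["dyad_id"].iloc[0])
        age = float(sub["age"].iloc[0])
        blocks = {
            Condition(c): records_from_frame(g) for c, g in sub.groupby("condition", sort=False)
        }
        alpha_friend = None
        if Condition.PREDICTED_FRIEND in blocks:
            alpha_friend = estimate_alpha_friend(blocks[Condition.PREDICTED_FRIEND][0], participant_id=str(pid))
        for condition, (records, cset) in blocks.items():
            if condition is Condition.PREDICTED_FRIEND:
                continue
            if condition in OPPOSITE_FAMILY:
                if alpha_friend is None:
                    raise ValueError(
                        f"participant {pid} has {condition.value} data but no PredictedFriend block"
                    )
                fit = fit_revised(records, alpha_friend=alpha_friend, participant_id=str(pid), condition=condition, dyad_id=dyad)
            else:
                fit = fit_original(records, participant_id=str(pid), condition=condition, dyad_id=dyad)
            fits.append(fit)
            summ = bhv.summarize(records, cset, participant_id=str(pid))
            behavior_rows.append(
                {
                    "participant_id": str(pid),
                    "dyad_id": dyad,
                    "age": age,
                    "condition": condition.value,
                    "prop_risky": summ.prop_risky,
                    "earnings": summ.earnings,
                    "earnings_prop": summ.earnings_prop,
                }
            )
    return fits, pd.DataFrame(behavior_rows)


def analysis_table(
    fits: list[FitResult],
    behavior: pd.DataFrame,
    flags,
    ages: pd.DataFrame,
) -> pd.DataFrame:
    """Per participant x condition analysis rows with exclusions applied."""
    fit_df = fits_to_frame(fits, flags)
    merged = fit_df.merge(behavior, on=["participant_id", "dyad_id", "condition"], how="left")
    kept = merged.loc[~merged["excluded"].fillna(False).astype(bool)].copy()
    return kept


@dataclass
class ReportBundle:
    out_dir: Path
    fits: pd.DataFrame
    behavior: pd.DataFrame
    analyses: dict[str, object]
    summary_path: Path


def _plot_band(band, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(band.ages, band.lower, band.upper, alpha=0.3)
    ax.plot(band.ages, band.estimate)
    ax.axhline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("age (years)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis: simulate/load -> fit -> exclude -> behaviour
    -> age trends, writing per-stage CSVs, figures, and a text summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary_lines = [f"dyadrisk run, config hash {chash}, seed {config.seed}"]

    if config.input_path:
        table = read_trial_table(config.input_path)
        truth = None
    else:
        cohort_cfg = config.cohort
        cohort = generate_cohort(cohort_cfg)
        table = generate_study_dataset(cohort, seed=config.seed, config=cohort_cfg)
        truth = cohort_truth_frame(cohort)
        _write_csv(truth, out / "cohort_truth.csv", chash)
        _write_csv(table, out / "trials.csv", chash)
    summary_lines.append(f"participants: {table['participant_id'].nunique()}, rows: {len(table)}")

    fits, behavior = fit_participants(table)
    flags = apply_exclusions(fits, config.exclusions)
    fit_df = fits_to_frame(fits, flags)
    ages = table.groupby("participant_id", as_index=False)["age"].first()
    fit_df = fit_df.merge(ages, on="participant_id", how="left")
    behavior = behavior.copy()
    _write_csv(fit_df, out / "fits.csv", chash)
    _write_csv(behavior, out / "behavior.csv", chash)
    n_excluded = int(fit_df["excluded"].fillna(False).astype(bool).sum())
    summary_lines.append(
        f"fits: {len(fit_df)}; excluded: {n_excluded} ({n_excluded / max(len(fit_df),1):.1%})"
    )

    kept = fit_df.loc[~fit_df["excluded"].fillna(False).astype(bool)].copy()
    kept = kept.merge(
        behavior[["participant_id", "condition", "prop_risky", "earnings", "earnings_prop"]],
        on=["participant_id", "condition"],
        how="left",
    )

    analyses: dict[str, object] = {}
    draws = config.n_band_draws
    bd = config.basis_dim

    def subtable(conditions: list[Condition]) -> pd.DataFrame:
        names = [c.value for c in conditions]
        sub = kept.loc[kept["condition"].isin(names)].copy()
        sub["condition"] = pd.Categorical(sub["condition"], categories=names)
        sub = sub.sort_values(["condition", "participant_id"])
        sub["condition"] = sub["condition"].astype(str)
        return sub

    # Q1: baseline age trend (alpha and earnings proportion)
    base = subtable([Condition.BASELINE])
    q1_fit = gam.fit_age_smooth(base, "alpha", basis_dim=bd)
    q1_band = gam.derivative_simultaneous_band(q1_fit, n_draws=draws, seed=config.seed)
    analyses["q1_alpha_derivative"] = q1_band
    _write_csv(q1_band.to_frame(), out / "q1_baseline_alpha_derivative.csv", chash)
    q1_earn_fit = gam.fit_proportion_model(base, "earnings_prop", basis_dim=bd)
    q1_earn_band = gam.derivative_simultaneous_band(q1_earn_fit, n_draws=draws, seed=config.seed)
    analyses["q1_earnings_derivative"] = q1_earn_band
    _write_csv(q1_earn_band.to_frame(), out / "q1_baseline_earnings_derivative.csv", chash)
    summary_lines.append(
        "Q1 baseline: mean alpha "
        f"{base['alpha'].mean():.3f}, mean earnings ${base['earnings'].mean():.2f}; "
        f"alpha derivative windows: {gam.significant_windows(q1_band) or 'none'}"
    )

    # Q2: Identical / Opposite vs Baseline (never Opposite vs Identical)
    part1 = subtable([Condition.BASELINE, Condition.IDENTICAL, Condition.OPPOSITE])
    q2_fit = gam.fit_age_smooth(part1, "alpha", basis_dim=bd)
    analyses["q2_fit"] = q2_fit
    for cond in (Condition.IDENTICAL, Condition.OPPOSITE):
        band = gam.difference_smooth(q2_fit, cond.value, Condition.BASELINE.value, n_draws=draws, seed=config.seed)
        analyses[f"q2_alpha_{cond.value}_vs_baseline"] = band
        _write_csv(band.to_frame(), out / f"q2_alpha_{cond.value}_vs_baseline.csv", chash)
        summary_lines.append(
            f"Q2 alpha {cond.value} vs Baseline: windows {band.significant_intervals or 'none'}"
        )
        if config.make_figures:
            _plot_band(band, f"alpha: {cond.value} - Baseline", out / f"q2_alpha_{cond.value}_vs_baseline.png")
    q2_earn_fit = gam.fit_proportion_model(part1, "earnings_prop", basis_dim=bd)
    for cond in (Condition.IDENTICAL, Condition.OPPOSITE):
        band = gam.difference_smooth(q2_earn_fit, cond.value, Condition.BASELINE.value, n_draws=draws, seed=config.seed)
        analyses[f"q2_earnings_{cond.value}_vs_baseline"] = band
        _write_csv(band.to_frame(), out / f"q2_earnings_{cond.value}_vs_baseline.csv", chash)
        summary_lines.append(
            f"Q2 earnings {cond.value} vs Baseline: windows {band.significant_intervals or 'none'}"
        )

    # Q3: observation within context (4-level factor, no 2x2 interaction)
    part2 = subtable(
        [
            Condition.OBSERVED_IDENTICAL,
            Condition.UNOBSERVED_IDENTICAL,
            Condition.OBSERVED_OPPOSITE,
            Condition.UNOBSERVED_OPPOSITE,
        ]
    )
    if len(part2):
        q3_fit = gam.fit_age_smooth(part2, "alpha", basis_dim=bd)
        analyses["q3_fit"] = q3_fit
        for a, b, label in (
            (Condition.OBSERVED_IDENTICAL, Condition.UNOBSERVED_IDENTICAL, "identical"),
            (Condition.OBSERVED_OPPOSITE, Condition.UNOBSERVED_OPPOSITE, "opposite"),
        ):
            band = gam.difference_smooth(q3_fit, a.value, b.value, n_draws=draws, seed=config.seed)
            analyses[f"q3_alpha_observation_{label}"] = band
            _write_csv(band.to_frame(), out / f"q3_alpha_observation_{label}.csv", chash)
            summary_lines.append(
                f"Q3 alpha observation ({label}): windows {band.significant_intervals or 'none'}"
            )

    # Q4: friend-weight age trend in the Opposite condition
    opp = subtable([Condition.OPPOSITE]).dropna(subset=["w"])
    q4_fit = gam.fit_age_smooth(opp, "w", basis_dim=bd)
    q4_band = gam.derivative_simultaneous_band(q4_fit, n_draws=draws, seed=config.seed)
    analyses["q4_w_derivative"] = q4_band
    analyses["q4_fit"] = q4_fit
    _write_csv(q4_band.to_frame(), out / "q4_w_derivative.csv", chash)
    slope = np.polyfit(opp["age"], opp["w"], 1)[0]
    summary_lines.append(
        f"Q4 friend weight: mean w {opp['w'].mean():.3f}, linear age slope {slope:+.4f}, "
        f"smooth edf {q4_fit.edf_by_term.get('s(age)', float('nan')):.2f}, "
        f"derivative windows: {gam.significant_windows(q4_band) or 'none'}"
    )
    if config.make_figures:
        _plot_band(q4_band, "d w / d age", out / "q4_w_derivative.png")

    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    return ReportBundle(out_dir=out, fits=fit_df, behavior=behavior, analyses=analyses, summary_path=summary_path)
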