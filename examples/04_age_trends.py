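"""Age-trend inference: smooths, derivatives, and condition differences.

Generates a small synthetic dyad cohort with a built-in early-adolescent
shift toward risk acceptance in the Opposite context, fits penalized-spline
age models to the per-participant measures, and reports where simultaneous
95% bands say the conditions differ. Uses a reduced cohort (24 dyads) and
choice proportions as the dependent variable so the whole script runs in
about a minute; the full pipeline does the same with fitted model parameters.
"""

import numpy as np

from dyadrisk import (
    CohortConfig,
    difference_smooth,
    fit_age_smooth,
    generate_cohort,
    generate_study_dataset,
)

cfg = CohortConfig(n_dyads=24, seed=3)
cohort = generate_cohort(cfg)
table = generate_study_dataset(cohort, seed=3, config=cfg)

# model-free risky-choice proportions per participant x condition
prop = (
    table[table.condition.isin(["Baseline", "Identical", "Opposite"])]
    .groupby(["participant_id", "dyad_id", "age", "condition"], as_index=False)["chose_risky"]
    .mean()
    .rename(columns={"chose_risky": "prop_risky"})
)

fit = fit_age_smooth(prop, "prop_risky", basis_dim=8)
print("parametric condition effects (vs Baseline):")
print(fit.parametric.round(3).to_string(index=False))

band = difference_smooth(fit, "Opposite", "Baseline", n_draws=5000, seed=0)
windows = band.significant_intervals
print(f"\nOpposite - Baseline difference at age 12: {band.estimate[0]:+.3f}")
print(f"Opposite - Baseline difference at age 22.8: {band.estimate[-1]:+.3f}")
if windows:
    spans = ", ".join(f"{a:.1f}-{b:.1f}y" for a, b in windows)
    print(f"simultaneous 95% band excludes zero at: {spans}")
else:
    print("simultaneous 95% band includes zero everywhere (no detectable window)")
print(
    "\nA window at the youngest ages mirrors the generator's built-in\n"
    "early-adolescent shift (at 24 dyads, stray windows can also appear at\n"
    "the sparse age edges); the Identical condition, generated with only a\n"
    "tiny offset, should show none:",
    difference_smooth(fit, "Identical", "Baseline", n_draws=5000, seed=0).significant_intervals or "none",
)

# the friend-outcome weight declines with age by construction
ages = np.array([a.age for a in cohort])
w = np.array([a.true_w for a in cohort])
print(f"\ngenerative friend-weight age slope: {np.polyfit(ages, w, 1)[0]:+.4f} per year")
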