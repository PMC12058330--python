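import numpy as np
import pytest

from dyadrisk.cohort import CohortConfig, generate_cohort, generate_study_dataset, cohort_truth_frame
from dyadrisk.fitting import apply_exclusions, fits_to_frame
from dyadrisk.pipeline import fit_participants
from dyadrisk.task import Condition, build_choice_set


@pytest.fixture(scope="session")
def standard_set():
    """The canonical 35-trial choice set."""
    return build_choice_set(Condition.BASELINE, seed=1)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (64 dyads, 128 participants)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def study_fits(default_cohort):
    """Full study dataset for the default cohort, fitted per participant.

    Expensive (several minutes); shared across the end-to-end checks. Returns
    (fit table incl. exclusions and ages, behaviour table, truth table).
    """
    cfg = CohortConfig(seed=0)
    table = generate_study_dataset(default_cohort, seed=0, config=cfg)
    fits, behavior = fit_participants(table)
    flags = apply_exclusions(fits)
    fit_df = fits_to_frame(fits, flags)
    ages = table.groupby("participant_id", as_index=False)["age"].first()
    fit_df = fit_df.merge(ages, on="participant_id", how="left")
    truth = cohort_truth_frame(default_cohort)
    return fit_df, behavior.merge(ages, on="participant_id", how="left"), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
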