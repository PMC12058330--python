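"""End-to-end run: simulate a cohort, fit, exclude, and analyse age trends.

Equivalent to `dyadrisk run-all` from the shell. Uses a reduced cohort
(16 dyads) and a coarser spline basis so the example finishes in a couple of
minutes; the defaults (64 dyads, basis 10, 10,000 band draws) emulate a
full study and take ~10 minutes on one core.
"""

from dyadrisk import PipelineConfig, run_pipeline
from dyadrisk.cohort import CohortConfig

config = PipelineConfig(
    cohort=CohortConfig(n_dyads=16, seed=1),
    seed=1,
    out_dir="scratch/example_run",
    n_band_draws=2000,
    basis_dim=6,
)
bundle = run_pipeline(config)
print(bundle.summary_path.read_text())
print(f"stage outputs in {bundle.out_dir}/ (CSVs carry the config hash in a header comment)")
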