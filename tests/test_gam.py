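"""Penalized-spline age models, derivative and difference bands."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from dyadrisk import gam


def make_table(rng, n=120, f=None, noise=0.12, conditions=("A",), cond_effects=None, dyad_sd=0.08):
    """Simulated participant x condition table with known age trend f(age)."""
    f = f or (lambda a: np.zeros_like(a))
    cond_effects = cond_effects or {}
    age = rng.uniform(12, 22.8, n)
    dyad = np.repeat([f"d{i:03d}" for i in range((n + 1) // 2)], 2)[:n]
    dyad_eff = {d: rng.normal(0, dyad_sd) for d in np.unique(dyad)}
    frames = []
    for cond in conditions:
        eff = cond_effects.get(cond, lambda a: np.zeros_like(a))
        y = f(age) + eff(age) + np.array([dyad_eff[d] for d in dyad]) + rng.normal(0, noise, n)
        frames.append(
            pd.DataFrame(
                {
                    "age": age,
                    "y": y,
                    "condition": cond,
                    "participant_id": [f"p{i:03d}" for i in range(n)],
                    "dyad_id": dyad,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestFitAgeSmooth:
    def test_constant_dv_flat_smooth(self, rng):
        df = make_table(rng, f=lambda a: np.full_like(a, 0.5), noise=0.05)
        fit = gam.fit_age_smooth(df, "y", condition_col=None)
        assert fit.edf_by_term["s(age)"] < 1.6
        band = gam.derivative_simultaneous_band(fit, n_draws=2000, seed=0)
        assert not band.excludes_zero().any()

    def test_linear_trend_slope_recovered(self, rng):
        df = make_table(rng, f=lambda a: 0.1 * a, noise=0.1)
        fit = gam.fit_age_smooth(df, "y", condition_col=None)
        band = gam.derivative_simultaneous_band(fit, n_draws=2000, seed=0)
        # derivative close to 0.1 over the central age range
        inner = (band.ages > 14) & (band.ages < 21)
        assert np.allclose(band.estimate[inner], 0.1, atol=0.04)
        assert band.excludes_zero()[inner].mean() > 0.9

    def test_insufficient_distinct_ages_error(self, rng):
        df = make_table(rng, n=30)
        df["age"] = np.repeat(np.arange(5), 6).astype(float)[:30]
        with pytest.raises(ValueError, match="distinct ages"):
            gam.fit_age_smooth(df, "y", condition_col=None)

    def test_self_difference_identically_zero(self, rng):
        df = make_table(rng, conditions=("A", "B"), cond_effects={"B": lambda a: 0.1 + 0 * a})
        fit = gam.fit_age_smooth(df, "y")
        band = gam.difference_smooth(fit, "A", "A", n_draws=500, seed=0)
        assert np.allclose(band.estimate, 0.0)
        assert not band.excludes_zero().any()

    def test_duplicated_condition_data_gives_matching_smooths(self, rng):
        base = make_table(rng, n=100, f=lambda a: 0.05 * a)
        dup = base.copy()
        dup["condition"] = "B"
        fit = gam.fit_age_smooth(pd.concat([base, dup], ignore_index=True), "y")
        ages = np.linspace(12.5, 22.3, 50)
        pa = fit.predict(ages, "A")
        pb = fit.predict(ages, "B")
        assert np.allclose(pa, pb, atol=1e-3)

    def test_antisymmetric_difference(self, rng):
        df = make_table(rng, conditions=("A", "B"), cond_effects={"B": lambda a: 0.2 - 0.01 * a})
        fit = gam.fit_age_smooth(df, "y")
        ab = gam.difference_smooth(fit, "A", "B", n_draws=500, seed=1)
        ba = gam.difference_smooth(fit, "B", "A", n_draws=500, seed=1)
        assert np.allclose(ab.estimate, -ba.estimate)

    def test_unknown_condition_rejected(self, rng):
        df = make_table(rng, conditions=("A", "B"))
        fit = gam.fit_age_smooth(df, "y")
        with pytest.raises(ValueError, match="not among fitted levels"):
            gam.difference_smooth(fit, "A", "C")


class TestBands:
    def test_simultaneous_contains_pointwise(self, rng):
        from scipy import stats

        df = make_table(rng, f=lambda a: 0.02 * (a - 17) ** 2)
        fit = gam.fit_age_smooth(df, "y", condition_col=None)
        band = gam.derivative_simultaneous_band(fit, n_draws=4000, seed=3)
        z = stats.norm.ppf(0.975)
        assert band.crit >= z  # simultaneous widening factor
        assert np.all(band.lower <= band.estimate) and np.all(band.estimate <= band.upper)

    def test_strong_trend_yields_windows_and_read_off(self, rng):
        df = make_table(rng, f=lambda a: 0.3 * a, noise=0.1)
        fit = gam.fit_age_smooth(df, "y", condition_col=None)
        band = gam.derivative_simultaneous_band(fit, n_draws=2000, seed=0)
        windows = gam.significant_windows(band)
        assert windows, "steep trend should produce a significant window"
        lo, hi = windows[0][0], windows[-1][1]
        assert hi - lo > 0.8 * (band.ages[-1] - band.ages[0])

    def test_windows_are_exact_run_read_off(self):
        ages = np.linspace(12, 22, 100)
        est = np.zeros(100)
        lower, upper = est - 1.0, est + 1.0
        lower[10:31] = 0.1  # band excludes zero on points 10..30 only
        upper[10:31] = 0.3
        est2 = est.copy()
        est2[10:31] = 0.2
        band = gam.DerivativeBand(ages=ages, estimate=est2, lower=lower, upper=upper, se=np.ones(100), crit=2.0)
        windows = gam.significant_windows(band)
        assert len(windows) == 1
        assert windows[0] == (pytest.approx(ages[10]), pytest.approx(ages[30]))

    def test_derivative_integrates_back_to_smooth(self, rng):
        """Trapezoid integration of the fitted derivative reconstructs the
        fitted curve to within 1% of its range."""
        df = make_table(rng, f=lambda a: np.sin((a - 12) / 3) * 0.5, noise=0.08, n=160)
        fit = gam.fit_age_smooth(df, "y", condition_col=None)
        band = gam.derivative_simultaneous_band(fit, n_points=400, n_draws=100, seed=0)
        curve = fit.predict(band.ages)
        recon = curve[0] + np.concatenate(
            [[0.0], np.cumsum((band.estimate[1:] + band.estimate[:-1]) / 2 * np.diff(band.ages))]
        )
        rng_y = curve.max() - curve.min()
        assert np.max(np.abs(recon - curve)) < 0.01 * rng_y


class TestProportionModel:
    def test_boundary_proportions_squeezed(self, rng):
        df = make_table(rng, f=lambda a: np.full_like(a, 0.9), noise=0.05)
        df["y"] = df["y"].clip(0.5, 1.0)
        df.loc[df.index[:5], "y"] = 1.0  # exact boundary values present
        fit = gam.fit_proportion_model(df, "y", condition_col=None)
        assert fit.boundary_squeezed
        assert fit.family == "beta"

    def test_dv_outside_unit_interval_rejected(self, rng):
        df = make_table(rng, f=lambda a: np.full_like(a, 1.5))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            gam.fit_proportion_model(df, "y", condition_col=None)

    def test_condition_effect_on_logit_scale_recovered(self, rng):
        from scipy.special import expit

        n = 128
        age = rng.uniform(12, 22.8, n)
        frames = []
        for cond, eta0 in (("Baseline", 2.4), ("Opposite", 2.4 - 0.8)):
            y = expit(eta0 + rng.normal(0, 0.45, n))
            frames.append(
                pd.DataFrame(
                    {
                        "age": age,
                        "y": y,
                        "condition": cond,
                        "participant_id": [f"p{i}" for i in range(n)],
                        "dyad_id": [f"d{i//2}" for i in range(n)],
                    }
                )
            )
        fit = gam.fit_proportion_model(pd.concat(frames, ignore_index=True), "y")
        row = fit.parametric.set_index("term").loc["condition:Opposite"]
        assert row["estimate"] == pytest.approx(-0.8, abs=0.25)
        assert row["z"] < -3
        assert row["p"] < 0.01

    def test_null_condition_rarely_significant(self, rng):
        """Type-I control of the parametric z test: two identically distributed
        conditions should be flagged at roughly the nominal rate."""
        from scipy.special import expit

        hits = 0
        reps = 40
        for rep in range(reps):
            n = 60
            age = rng.uniform(12, 22.8, n)
            frames = []
            for cond in ("A", "B"):
                y = expit(2.0 + rng.normal(0, 0.5, n))
                frames.append(
                    pd.DataFrame(
                        {
                            "age": age,
                            "y": y,
                            "condition": cond,
                            "participant_id": [f"p{i}" for i in range(n)],
                            "dyad_id": [f"d{i//2}" for i in range(n)],
                        }
                    )
                )
            fit = gam.fit_proportion_model(pd.concat(frames, ignore_index=True), "y")
            p = fit.parametric.set_index("term").loc["condition:B", "p"]
            hits += p < 0.05
        assert hits / reps <= 0.2  # majority non-significant at nominal alpha


class TestAgainstIndependentImplementations:
    def test_matches_mgcv_reml_fit(self, rng, tmp_path):
        """Gaussian REML smooth agrees with R mgcv on the same data."""
        df = make_table(rng, n=140, f=lambda a: 0.02 * (a - 16) ** 2, noise=0.1)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(mgcv))
                df <- read.csv('{csv}')
                df$dyad_id <- as.factor(df$dyad_id)
                m <- gam(y ~ s(age, k=10, bs='bs') + s(dyad_id, bs='re'), data=df, method='REML')
                grid <- data.frame(age=seq(quantile(df$age,0.05), quantile(df$age,0.95), length.out=25),
                                   dyad_id=df$dyad_id[1])
                p <- predict(m, newdata=grid, exclude='s(dyad_id)', newdata.guaranteed=TRUE)
                cat(sprintf('%.6f\\n', p))
                """
            )
        )
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        mgcv_pred = np.array([float(x) for x in out.stdout.split()])
        fit = gam.fit_age_smooth(df, "y", condition_col=None)
        lo, hi = np.quantile(df["age"], [0.05, 0.95])
        ours = fit.predict(np.linspace(lo, hi, 25))
        rng_y = mgcv_pred.max() - mgcv_pred.min()
        assert np.corrcoef(ours, mgcv_pred)[0, 1] > 0.995
        assert np.max(np.abs(ours - mgcv_pred)) < 0.05 * max(rng_y, 0.5)

    def test_derivative_windows_match_parametric_bootstrap(self, rng):
        """Simultaneous derivative windows agree with a brute-force parametric
        bootstrap (simulate-from-fit, refit, max-deviation quantile) on a
        small fixture."""
        n = 40
        age = np.sort(rng.uniform(12, 22.8, n))
        y = 0.12 * age + rng.normal(0, 0.15, n)
        df = pd.DataFrame({"age": age, "y": y, "participant_id": [f"p{i}" for i in range(n)]})
        fit = gam.fit_age_smooth(df, "y", condition_col=None, dyad_col=None, basis_dim=8)
        band = gam.derivative_simultaneous_band(fit, n_draws=4000, seed=0)

        curve = fit.predict(age)
        sigma = np.sqrt(fit.scale)
        h = 1e-4 * (age.max() - age.min())
        Xd = (
            fit.design.population_design(band.ages + h, None)
            - fit.design.population_design(band.ages - h, None)
        ) / (2 * h)
        boot = np.empty((500, len(band.ages)))
        for b in range(500):
            yb = curve + rng.normal(0, sigma, n)
            fb = gam.fit_age_smooth(df.assign(y=yb), "y", condition_col=None, dyad_col=None, basis_dim=8)
            boot[b] = Xd @ fb.beta
        se_boot = boot.std(axis=0)
        dev = np.abs(boot - Xd @ fit.beta) / se_boot
        crit_boot = np.quantile(dev.max(axis=1), 0.95)
        excl_boot = np.abs(band.estimate) > crit_boot * se_boot
        disagree = int(np.sum(excl_boot != band.excludes_zero()))
        assert disagree <= 10  # of 100 evaluation points
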