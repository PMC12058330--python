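"""Utility models, logistic choice rule, likelihood, and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadrisk.models import (
    ChoiceRecord,
    Model,
    OriginalParams,
    PTParams,
    SocialParams,
    expected_utility,
    log_likelihood,
    opposite_pair_utility,
    p_choose_risky,
    probability_weight,
    pt_expected_utility,
    simulate_choices,
)
from dyadrisk.task import Condition, Lottery, build_choice_set


def brute_force_loglik(records, model, params):
    """Independent oracle: per-trial formula evaluation with math.* scalars."""
    total = 0.0
    for r in records:
        p, v = r.trial.risky.p_win, r.trial.risky.amount
        s = r.trial.safe.amount
        if model is Model.ORIGINAL:
            eu_r = p * v**params.alpha
            eu_s = s**params.alpha
        elif model is Model.REVISED:
            eu_r = (1 - params.w) * p * v**params.alpha + params.w * s**params.alpha_friend
            eu_s = (1 - params.w) * s**params.alpha + params.w * p * v**params.alpha_friend
        else:
            pi = p**params.gamma / (p**params.gamma + (1 - p) ** params.gamma) ** (1 / params.gamma)
            eu_r = pi * v**params.alpha
            eu_s = s**params.alpha
        x = params.beta * (eu_s - eu_r)
        # scalar stable log-probabilities: log P(risky) = -log(1+e^x)
        log_pr = -x - math.log1p(math.exp(-x)) if x > 0 else -math.log1p(math.exp(x))
        log_ps = -math.log1p(math.exp(-x)) if x > 0 else x - math.log1p(math.exp(x))
        total += log_pr if r.chose_risky else log_ps
    return total


class TestExpectedUtility:
    def test_certainty_linear(self):
        assert expected_utility(Lottery(1.0, 5), 1.0) == 5

    def test_equals_ev_at_alpha_one(self):
        assert expected_utility(Lottery(0.5, 20), 1.0) == 10

    def test_risk_averse_curvature(self):
        assert expected_utility(Lottery(0.75, 50), 0.55) == pytest.approx(6.449, abs=5e-3)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            expected_utility(Lottery(0.5, 20), 0.0)


class TestOppositePairUtility:
    def test_self_only_limit(self):
        p = SocialParams(alpha=0.7, beta=1, w=0.0, alpha_friend=1.2)
        assert opposite_pair_utility(Lottery(0.5, 20), Lottery(1, 5), p) == pytest.approx(
            expected_utility(Lottery(0.5, 20), 0.7)
        )

    def test_friend_only_limit(self):
        p = SocialParams(alpha=0.7, beta=1, w=1.0, alpha_friend=1.2)
        assert opposite_pair_utility(Lottery(0.5, 20), Lottery(1, 5), p) == pytest.approx(
            expected_utility(Lottery(1, 5), 1.2)
        )

    def test_symmetric_at_equal_exponents_and_half_weight(self):
        p = SocialParams(alpha=1.0, beta=1, w=0.5, alpha_friend=1.0)
        a = opposite_pair_utility(Lottery(0.5, 20), Lottery(1, 5), p)
        b = opposite_pair_utility(Lottery(1, 5), Lottery(0.5, 20), p)
        assert a == pytest.approx(7.5)
        assert b == pytest.approx(7.5)


class TestChoiceRule:
    def test_indifference_gives_half(self):
        assert p_choose_risky(3.0, 3.0, beta=9.0) == 0.5

    def test_zero_beta_gives_half(self):
        assert p_choose_risky(1.0, 99.0, beta=0.0) == 0.5

    def test_hand_value(self):
        assert p_choose_risky(4.0, 5.0, beta=2.0) == pytest.approx(1 / (1 + math.exp(-2)))

    def test_extreme_arguments_stay_finite_and_ordered(self):
        lo = p_choose_risky(1e4, 0.0, beta=1.0)
        hi = p_choose_risky(0.0, 1e4, beta=1.0)
        assert 0.0 <= lo < 1e-300 or lo == 0.0  # underflow is graceful
        assert hi <= 1.0 and hi > 1 - 1e-12

    @given(
        gap=st.floats(-50, 50),
        beta=st.floats(0, 20),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_in_utility_gap(self, gap, beta):
        base = p_choose_risky(5.0, 5.0 + gap, beta)
        more = p_choose_risky(5.0, 5.0 + gap + 1.0, beta)
        assert more >= base - 1e-12


class TestProbabilityWeighting:
    def test_identity_at_gamma_one(self):
        p = np.array([0.1, 0.5, 0.9])
        assert probability_weight(p, 1.0) == pytest.approx(p)

    def test_endpoints_preserved(self):
        for g in (0.4, 0.61, 1.3):
            assert probability_weight(0.0, g) == 0.0
            assert probability_weight(1.0, g) == pytest.approx(1.0)

    def test_hand_value_tversky_kahneman(self):
        g = 0.61
        pi = 0.1**g / (0.1**g + 0.9**g) ** (1 / g)
        assert pt_expected_utility(Lottery(0.1, 10), PTParams(alpha=1.0, gamma=g, beta=1)) == pytest.approx(10 * pi)

    def test_pt_reduces_to_eu_at_gamma_one(self):
        lot = Lottery(0.75, 40)
        assert pt_expected_utility(lot, PTParams(alpha=0.8, gamma=1.0, beta=1)) == pytest.approx(
            expected_utility(lot, 0.8)
        )


class TestLogLikelihood:
    def test_chance_model(self, standard_set):
        records = [ChoiceRecord(t, i % 2 == 0) for i, t in enumerate(standard_set.trials)]
        params = OriginalParams(alpha=0.7, beta=0.0)
        assert log_likelihood(records, Model.ORIGINAL, params) == pytest.approx(35 * math.log(0.5))

    def test_consistent_choices_approach_zero_at_high_beta(self, standard_set):
        alpha = 0.8
        records = [
            ChoiceRecord(t, expected_utility(t.risky, alpha) > expected_utility(t.safe, alpha))
            for t in standard_set.trials
        ]
        ll = log_likelihood(records, Model.ORIGINAL, OriginalParams(alpha=alpha, beta=40.0))
        assert -0.5 < ll <= 0

    def test_matches_brute_force_oracle_on_random_draws(self, standard_set, rng):
        """Vectorized likelihood equals direct per-trial evaluation to 1e-10."""
        opp_set = build_choice_set(Condition.OPPOSITE, seed=4)
        for _ in range(100):
            model = Model(rng.choice(["original", "revised", "prospect"]))
            if model is Model.ORIGINAL:
                params = OriginalParams(alpha=rng.uniform(0.05, 3), beta=rng.uniform(0, 10))
            elif model is Model.REVISED:
                params = SocialParams(
                    alpha=rng.uniform(0.05, 2),
                    beta=rng.uniform(0, 10),
                    w=rng.uniform(0, 1),
                    alpha_friend=rng.uniform(0.05, 2),
                )
            else:
                params = PTParams(alpha=rng.uniform(0.05, 2), gamma=rng.uniform(0.3, 1.5), beta=rng.uniform(0, 10))
            cset = opp_set if model is Model.REVISED else standard_set
            records = [ChoiceRecord(t, bool(rng.integers(2))) for t in cset.trials]
            # 1e-10 absolute, loosened to relative only when |ll| is so large
            # that doubles cannot represent absolute 1e-10 differences
            assert log_likelihood(records, model, params) == pytest.approx(
                brute_force_loglik(records, model, params), abs=1e-10, rel=1e-12
            )

    def test_revised_nests_original_at_zero_weight(self, standard_set, rng):
        """With w = 0 the social model reproduces the original likelihood exactly."""
        for _ in range(25):
            alpha, beta = rng.uniform(0.1, 2.5), rng.uniform(0, 12)
            records = [ChoiceRecord(t, bool(rng.integers(2))) for t in standard_set.trials]
            ll_orig = log_likelihood(records, Model.ORIGINAL, OriginalParams(alpha=alpha, beta=beta))
            ll_rev = log_likelihood(
                records, Model.REVISED, SocialParams(alpha=alpha, beta=beta, w=0.0, alpha_friend=1.7)
            )
            assert ll_rev == pytest.approx(ll_orig, abs=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], Model.ORIGINAL, OriginalParams(alpha=1, beta=1))


class TestSimulation:
    def test_deterministic_limit_tracks_expected_value(self, standard_set):
        records = simulate_choices(OriginalParams(alpha=1.0, beta=1e4), Model.ORIGINAL, standard_set, seed=0)
        for r in records:
            assert r.chose_risky == (r.trial.risky.expected_value > 5)

    def test_chance_limit(self, standard_set):
        rate = np.mean(
            [
                r.chose_risky
                for s in range(60)
                for r in simulate_choices(OriginalParams(alpha=1, beta=0.0), Model.ORIGINAL, standard_set, seed=s)
            ]
        )
        assert rate == pytest.approx(0.5, abs=0.03)

    def test_seed_reproducibility(self, standard_set):
        p = OriginalParams(alpha=0.6, beta=2.0)
        a = simulate_choices(p, Model.ORIGINAL, standard_set, seed=11)
        b = simulate_choices(p, Model.ORIGINAL, standard_set, seed=11)
        assert [r.chose_risky for r in a] == [r.chose_risky for r in b]

    def test_alpha_monotonicity_of_deterministic_preference(self, standard_set):
        """Raising alpha never flips a noise-free choice back from risky to
        safe: each trial's risky-vs-safe preference switches at most once, at
        its indifference point. (Choice *probabilities* are not monotone in
        alpha — the utility gap 5**a - p*v**a rises before it falls — so the
        monotonicity claim only holds for the preference sign.)"""
        from dyadrisk.task import deterministic_choice_vector

        prev = None
        for alpha in np.linspace(0.05, 4.0, 40):
            vec = np.array(deterministic_choice_vector(standard_set, alpha))
            if prev is not None:
                assert np.all(vec >= prev)  # risky-preferred is absorbing
            prev = vec
        # dominated lotteries are never preferred at any exponent
        dominated = np.array([t.risky.amount <= t.safe.amount for t in standard_set.trials])
        assert not np.any(np.array(deterministic_choice_vector(standard_set, 4.0))[dominated])
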