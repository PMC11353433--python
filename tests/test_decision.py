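"""Loss functions, posterior expected loss, ranking and target construction."""

import numpy as np
import pytest

from pelselect.bayes import PredictiveEnsemble
from pelselect.decision import (
    TargetSpec,
    build_target,
    category_mass_at_target,
    expected_deviation_loss,
    kl_loss,
    posterior_expected_loss,
    rank_and_select,
)


def _random_spd(rng, d):
    A = rng.normal(size=(d, d))
    return A @ A.T + d * np.eye(d) * 0.1


def _ensemble(mu, sigma=None, n_continuous=None, thresholds=()):
    mu = np.asarray(mu, dtype=float)
    S, n, d = mu.shape
    if sigma is None:
        sigma = np.broadcast_to(np.eye(d), (S, d, d)).copy()
    if n_continuous is None:
        n_continuous = d - len(thresholds)
    return PredictiveEnsemble(
        mu, np.asarray(sigma, dtype=float),
        np.array([f"c{i}" for i in range(n)]), n_continuous, list(thresholds),
    )


class TestKlLoss:
    def test_identical_distributions_give_zero(self, rng):
        S = _random_spd(rng, 3)
        mu = rng.normal(size=3)
        assert kl_loss(mu, S, TargetSpec(mu, S)) == pytest.approx(0.0, abs=1e-10)

    def test_univariate_closed_form(self):
        # unit variances, means one apart: KL = 0.5
        assert kl_loss([0.0], [[1.0]], TargetSpec([1.0], [[1.0]])) == pytest.approx(0.5)

    def test_asymmetry(self):
        t = TargetSpec([0.0], [[1.0]])
        fwd = kl_loss([0.0], [[4.0]], t)
        rev = kl_loss([0.0], [[1.0]], TargetSpec([0.0], [[4.0]]))
        assert fwd != pytest.approx(rev)

    def test_nonnegative_on_random_instances(self, rng):
        for _ in range(20):
            d = rng.integers(1, 5)
            t = TargetSpec(rng.normal(size=d), _random_spd(rng, d))
            assert kl_loss(rng.normal(size=d), _random_spd(rng, d), t) >= 0.0

    def test_singular_covariance_rejected(self):
        t = TargetSpec([0.0, 0.0], np.eye(2))
        with pytest.raises(ValueError, match="positive definite"):
            kl_loss([0.0, 0.0], np.zeros((2, 2)), t)

    def test_matches_monte_carlo_estimate(self):
        # one deep check here; the 20-instance sweep lives in the acceptance suite
        rng = np.random.default_rng(42)
        mu_t, S_t = rng.normal(size=3), _random_spd(rng, 3)
        mu_c, S_c = rng.normal(size=3), _random_spd(rng, 3)
        closed = kl_loss(mu_c, S_c, TargetSpec(mu_t, S_t))
        from scipy.stats import multivariate_normal as mvn

        x = rng.multivariate_normal(mu_t, S_t, size=200_000)
        log_ratio = mvn.logpdf(x, mu_t, S_t) - mvn.logpdf(x, mu_c, S_c)
        se = log_ratio.std(ddof=1) / np.sqrt(len(x))
        assert abs(closed - log_ratio.mean()) < 3 * se


class TestDeviationLoss:
    def test_zero_when_candidate_hits_target(self):
        t = TargetSpec([1.0, 2.0], np.eye(2), goals=("increase", "decrease"))
        assert expected_deviation_loss([1.0, 2.0], np.eye(2), t) == 0.0

    def test_exceeding_increase_goal_is_negative(self):
        t = TargetSpec([1.0], np.eye(1), goals=("increase",))
        assert expected_deviation_loss([1.5], np.eye(1), t) < 0.0

    def test_two_trait_hand_case(self):
        t = TargetSpec([1.0, -1.0], np.eye(2), goals=("increase", "decrease"))
        # increase: 1.0 - 0.5 = 0.5 ; decrease: 0.5 - (-1.0) = 1.5
        val = expected_deviation_loss([0.5, 0.5], np.eye(2), t)
        assert val == pytest.approx(2.0)

    def test_neutral_goal_contributes_nothing(self):
        t = TargetSpec([5.0], np.eye(1), goals=("neutral",))
        assert expected_deviation_loss([-100.0], np.eye(1), t) == 0.0


class TestPosteriorExpectedLoss:
    def test_single_draw_equals_that_loss(self, rng):
        mu = rng.normal(size=(1, 4, 2))
        pred = _ensemble(mu)
        t = TargetSpec(np.zeros(2), np.eye(2))
        pels = posterior_expected_loss(pred, t)
        for c in range(4):
            assert pels[c] == pytest.approx(kl_loss(mu[0, c], np.eye(2), t))

    def test_identical_draws_equal_common_loss(self, rng):
        one = rng.normal(size=(1, 3, 2))
        pred = _ensemble(np.repeat(one, 50, axis=0))
        t = TargetSpec(np.zeros(2), np.eye(2))
        single = posterior_expected_loss(_ensemble(one), t)
        assert np.allclose(posterior_expected_loss(pred, t), single)

    def test_matches_naive_loop_over_draws(self, rng):
        S, n, d = 100, 6, 3
        mu = rng.normal(size=(S, n, d))
        sigma = np.stack([_random_spd(rng, d) for _ in range(S)])
        pred = _ensemble(mu, sigma)
        t = TargetSpec(rng.normal(size=d), _random_spd(rng, d))
        pels = posterior_expected_loss(pred, t)
        naive = np.array(
            [np.mean([kl_loss(mu[s, c], sigma[s], t) for s in range(S)])
             for c in range(n)]
        )
        assert np.allclose(pels, naive)

    def test_ranking_invariant_to_constant_loss_shift(self, rng):
        mu = rng.normal(size=(20, 8, 2))
        pred = _ensemble(mu)
        t = TargetSpec(np.zeros(2), np.eye(2))
        base = posterior_expected_loss(pred, t)

        def shifted(mu_c, sigma_c, target):
            return kl_loss(mu_c, sigma_c, target) + 17.0

        shift = posterior_expected_loss(pred, t, loss=shifted)
        assert np.array_equal(np.argsort(base), np.argsort(shift))

    def test_monotone_agreement_with_gebv_ranking(self, rng):
        # single continuous trait, identity covariances, far-above target:
        # lowest PEL must equal highest posterior-mean breeding value
        mu = rng.normal(size=(50, 12, 1))
        pred = _ensemble(mu)
        t = TargetSpec([100.0], np.eye(1))
        pels = posterior_expected_loss(pred, t)
        gebv = pred.posterior_mean()[:, 0]
        assert np.array_equal(np.argsort(pels), np.argsort(-gebv))

    def test_selection_improves_true_merit(self, rng):
        # predictive means = true merit + noise: the selected set must carry
        # higher mean true merit than the pool (directional, over replicates)
        wins = 0
        for rep in range(5):
            truth = rng.normal(size=40)
            mu = truth[None, :, None] + rng.normal(0, 0.5, size=(30, 40, 1))
            pred = _ensemble(mu)
            t = TargetSpec([truth.max() + 1.0], np.eye(1))
            res = rank_and_select(posterior_expected_loss(pred, t), 0.3)
            if truth[res.selected].mean() > truth.mean():
                wins += 1
        assert wins >= 4


class TestRankAndSelect:
    def test_fraction_one_selects_all(self):
        res = rank_and_select([3.0, 1.0, 2.0], 1.0)
        assert res.selected.all()

    def test_argmin_selected(self):
        res = rank_and_select([0.3, 0.1, 0.2], 1 / 3)
        assert list(res.selected) == [False, True, False]
        assert list(res.rank) == [3, 1, 2]

    def test_fifty_candidates_fraction_point_two_selects_ten(self, rng):
        res = rank_and_select(rng.normal(size=50), 0.2)
        assert res.selected.sum() == 10

    def test_ties_broken_by_candidate_order(self):
        res = rank_and_select([1.0, 1.0, 0.5], 2 / 3, ids=["a", "b", "c"])
        assert list(res.selected_ids()) == ["c", "a"]

    def test_nan_pel_names_candidate(self):
        with pytest.raises(ValueError, match="'bad'"):
            rank_and_select([0.1, np.nan], 0.5, ids=["ok", "bad"])


class TestBuildTarget:
    def test_ordinal_top_category_margin(self, rng):
        thr = np.broadcast_to(np.array([-0.5, 0.7]), (10, 2)).copy()
        mu = rng.normal(size=(10, 5, 1))
        pred = _ensemble(mu, n_continuous=0, thresholds=[thr])
        t = build_target(pred, ("increase",), {0: 3}, margin=1.0)
        assert t.mean[0] == pytest.approx(1.7)

    def test_decrease_goal_takes_minimum_extreme(self, rng):
        mu = rng.normal(size=(10, 5, 1))
        pred = _ensemble(mu)
        t = build_target(pred, ("decrease",))
        assert t.mean[0] == pytest.approx(pred.posterior_mean()[:, 0].min())

    def test_target_mass_on_preferred_category(self):
        from scipy.special import ndtr

        mass = category_mass_at_target(1.7, [-0.5, 0.7], 3)
        assert mass == pytest.approx(float(ndtr(1.0)))
        assert mass == pytest.approx(0.841, abs=5e-4)

    def test_missing_goal_rejected(self, rng):
        pred = _ensemble(rng.normal(size=(5, 4, 2)))
        with pytest.raises(ValueError, match="goal"):
            build_target(pred, ("increase",))
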