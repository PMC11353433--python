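"""Gibbs sampler correctness: recovery, calibration, assembly, invariants."""

import numpy as np
import pytest
from scipy import integrate, stats

from pelselect.bayes import (
    McmcSettings,
    assemble_ccmm_predictive,
    category_probabilities,
    fit_gaussian_multitrait,
    fit_ordinal_probit,
    GaussianChain,
    OrdinalChain,
)

SHORT = McmcSettings(iterations=1200, burn_in=300, thin=3)


def _dosages(rng, n, p):
    return rng.binomial(2, 0.5, size=(n, p)).astype(float)


class TestGaussianMultitrait:
    def test_posterior_mean_matches_ols_when_n_much_larger_than_p(self):
        rng = np.random.default_rng(0)
        n, p = 200, 3
        X = _dosages(rng, n, p)
        beta_true = np.array([1.0, -0.5, 0.25])
        y = 2.0 + X @ beta_true + rng.normal(0, 0.05, size=n)
        chain = fit_gaussian_multitrait(X, y, SHORT, seed=1)
        Xd = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0][1:]
        post_mean = chain.beta.mean(axis=0)[:, 0]
        post_sd = chain.beta.std(axis=0)[:, 0]
        assert np.all(np.abs(post_mean - ols) < 3 * post_sd + 1e-8)

    def test_residual_correlation_recovery(self):
        rng = np.random.default_rng(2)
        n, p = 300, 40
        X = _dosages(rng, n, p)
        B = rng.normal(0, 0.1, size=(p, 2))
        Sig = np.array([[1.0, 0.8], [0.8, 1.0]])
        Y = X @ B + rng.multivariate_normal([0, 0], Sig, size=n)
        chain = fit_gaussian_multitrait(X, Y, SHORT, seed=3)
        Sm = chain.sigma.mean(axis=0)
        rho = Sm[0, 1] / np.sqrt(Sm[0, 0] * Sm[1, 1])
        assert abs(rho - 0.8) < 0.1

    def test_redundant_constant_column_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(4)
        n, p = 150, 30
        X = _dosages(rng, n, p)
        y = X @ rng.normal(0, 0.2, size=p) + rng.normal(0, 0.5, size=n)
        Xcand = _dosages(rng, 20, p)
        a = fit_gaussian_multitrait(X, y, SHORT, seed=5)
        b = fit_gaussian_multitrait(
            np.column_stack([X, np.ones(n)]), y, SHORT, seed=5
        )
        pred_a = assemble_ccmm_predictive(a, [], Xcand).posterior_mean()[:, 0]
        pred_b = assemble_ccmm_predictive(
            b, [], np.column_stack([Xcand, np.ones(20)])
        ).posterior_mean()[:, 0]
        assert np.abs(pred_a - pred_b).max() < 0.15 * y.std()

    def test_missing_responses_rejected(self, rng):
        X = _dosages(rng, 10, 3)
        Y = np.ones((10, 2))
        Y[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_gaussian_multitrait(X, Y, SHORT)

    def test_sigma_draws_symmetric_positive_definite(self):
        rng = np.random.default_rng(6)
        X = _dosages(rng, 80, 20)
        Y = rng.normal(size=(80, 3))
        chain = fit_gaussian_multitrait(X, Y, SHORT, seed=7)
        for S in chain.sigma:
            assert np.allclose(S, S.T)
            np.linalg.cholesky(S)  # raises if not PD

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(8)
        X = _dosages(rng, 60, 10)
        Y = rng.normal(size=(60, 2))
        a = fit_gaussian_multitrait(X, Y, SHORT, seed=9)
        b = fit_gaussian_multitrait(X, Y, SHORT, seed=9)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.sigma, b.sigma)

    def test_predictive_concentrates_under_low_noise(self):
        rng = np.random.default_rng(10)
        n, p = 200, 5
        X = _dosages(rng, n, p)
        y = X @ np.array([0.5, -0.3, 0.2, 0.1, -0.4]) + rng.normal(0, 0.02, size=n)
        chain = fit_gaussian_multitrait(X, y, SHORT, seed=11)
        pred = assemble_ccmm_predictive(chain, [], X[:5]).posterior_mean()[:, 0]
        assert np.abs(pred - y[:5]).max() < 0.1


class TestOrdinalProbit:
    @staticmethod
    def _simulate(rng, n=500, p=50, gamma=(-0.5, 0.7)):
        X = _dosages(rng, n, p)
        Xc = X - X.mean(axis=0)
        beta = rng.normal(0, np.sqrt(0.5 / Xc.var(axis=0).sum()), size=p)
        liab = Xc @ beta + rng.standard_normal(n)
        y = np.searchsorted(np.asarray(gamma), liab) + 1
        return X, y, beta

    def test_binary_collapse_matches_probit_reference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n, p = 400, 8
        X = _dosages(rng, n, p)
        Xc = X - X.mean(axis=0)
        eta = Xc @ rng.normal(0, 0.3, size=p)
        y = (eta + rng.standard_normal(n) > 0.2).astype(int) + 1
        chain = fit_ordinal_probit(X, y, 2, SHORT, seed=13)
        # model probability of category 2 at the training points
        eta_hat = (Xc @ chain.beta.T) - chain.thresholds[:, 0]
        p_model = stats.norm.cdf(eta_hat).mean(axis=1)
        ref = sm.Probit(y - 1, sm.add_constant(Xc)).fit(disp=0)
        p_ref = ref.predict(sm.add_constant(Xc))
        assert np.abs(p_model - p_ref).mean() < 0.03

    def test_threshold_recovery(self):
        rng = np.random.default_rng(14)
        X, y, _ = self._simulate(rng)
        chain = fit_ordinal_probit(X, y, 3, SHORT, seed=15)
        gam = chain.thresholds.mean(axis=0)
        assert abs(gam[0] + 0.5) < 0.25
        assert abs(gam[1] - 0.7) < 0.25

    def test_null_predictor_reproduces_base_rates(self):
        rng = np.random.default_rng(16)
        n = 600
        y = rng.integers(1, 4, size=n)
        X = np.zeros((n, 3))
        chain = fit_ordinal_probit(X, y, 3, SHORT, seed=17)
        probs = np.stack(
            [category_probabilities(0.0, g) for g in chain.thresholds]
        ).mean(axis=0)
        freqs = np.bincount(y, minlength=4)[1:] / n
        assert np.abs(probs - freqs).max() < 0.05

    def test_threshold_ordering_in_every_draw(self):
        rng = np.random.default_rng(18)
        X, y, _ = self._simulate(rng, n=200, p=20)
        chain = fit_ordinal_probit(X, y, 3, SHORT, seed=19)
        assert (np.diff(chain.thresholds, axis=1) > 0).all()

    def test_unobserved_category_error_names_it(self, rng):
        X = _dosages(rng, 20, 3)
        y = np.array([1, 3] * 10)
        with pytest.raises(ValueError, match="category 2"):
            fit_ordinal_probit(X, y, 3, SHORT)

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(20)
        X, y, _ = self._simulate(rng, n=150, p=10)
        a = fit_ordinal_probit(X, y, 3, SHORT, seed=21)
        b = fit_ordinal_probit(X, y, 3, SHORT, seed=21)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.thresholds, b.thresholds)


class TestCategoryProbabilities:
    def test_symmetry_at_zero(self):
        assert np.allclose(category_probabilities(0.0, [0.0]), [0.5, 0.5])

    def test_large_eta_concentrates_on_top_category(self):
        probs = category_probabilities(50.0, [-0.5, 0.7])
        assert probs[-1] > 1 - 1e-10

    def test_sums_to_one_and_nonnegative(self, rng):
        eta = rng.normal(size=100)
        probs = category_probabilities(eta, [-1.0, 0.0, 1.5])
        assert probs.shape == (100, 4)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_matches_quadrature_oracle(self):
        eta, gamma = 0.3, np.array([-0.5, 0.7])
        probs = category_probabilities(eta, gamma)
        edges = np.concatenate(([-np.inf], gamma, [np.inf]))
        for k in range(3):
            q, _ = integrate.quad(
                lambda l: stats.norm.pdf(l, loc=eta), edges[k], edges[k + 1]
            )
            assert abs(probs[k] - q) < 1e-8


class TestAssembleCcmm:
    @staticmethod
    def _hand_chains(p=2):
        g = GaussianChain(
            mu0=np.array([[1.0], [2.0]]),
            beta=np.array([[[0.5], [-0.5]], [[1.0], [0.0]]]),
            sigma=np.array([[[2.0]], [[3.0]]]),
            effect_var=np.ones((2, 1)),
            x_center=np.zeros(p),
        )
        o = OrdinalChain(
            beta=np.array([[0.1, 0.2], [-0.1, 0.3]]),
            thresholds=np.array([[0.0, 1.0], [0.1, 1.1]]),
            effect_var=np.ones(2),
            x_center=np.zeros(p),
            n_categories=3,
        )
        return g, o

    def test_hand_built_two_draw_stacking(self):
        g, o = self._hand_chains()
        X = np.array([[1.0, 2.0]])
        pred = assemble_ccmm_predictive(g, [o], X)
        # draw 1: continuous mean 1 + 1*0.5 + 2*(-0.5) = 0.5; latent 0.1 + 0.4
        assert np.allclose(pred.mu[0, 0], [0.5, 0.5])
        # draw 2: continuous 2 + 1*1.0 + 0 = 3.0; latent -0.1 + 0.6
        assert np.allclose(pred.mu[1, 0], [3.0, 0.5])
        assert np.allclose(pred.sigma[0], [[2.0, 0.0], [0.0, 1.0]])
        assert np.allclose(pred.sigma[1], [[3.0, 0.0], [0.0, 1.0]])

    def test_zero_ordinal_traits_equals_gaussian_predictive(self):
        g, _ = self._hand_chains()
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        pred = assemble_ccmm_predictive(g, [], X)
        assert pred.dim == 1
        expected = g.mu0[:, None, 0] + np.einsum("np,sp->sn", X, g.beta[:, :, 0])
        assert np.allclose(pred.mu[:, :, 0], expected)
        assert np.allclose(pred.sigma, g.sigma)

    def test_pure_cm_covariance_is_identity(self):
        _, o = self._hand_chains()
        pred = assemble_ccmm_predictive(None, [o, o], np.ones((3, 2)))
        assert np.allclose(pred.sigma, np.broadcast_to(np.eye(2), (2, 2, 2)))

    def test_mismatched_draw_counts_rejected(self):
        g, o = self._hand_chains()
        o_short = OrdinalChain(
            beta=o.beta[:1], thresholds=o.thresholds[:1],
            effect_var=o.effect_var[:1], x_center=o.x_center, n_categories=3,
        )
        with pytest.raises(ValueError, match="draw counts"):
            assemble_ccmm_predictive(g, [o_short], np.ones((1, 2)))

    def test_mismatched_markers_rejected(self):
        g, o = self._hand_chains()
        with pytest.raises(ValueError, match="markers"):
            assemble_ccmm_predictive(g, [o], np.ones((1, 5)))
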