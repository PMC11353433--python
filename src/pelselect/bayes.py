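"""Gibbs samplers for multi-trait genomic regression and the joint predictive.

Two models are fitted independently, mirroring how breeders run them in
practice:

* a multi-trait Gaussian ridge regression ``y_i ~ MVN(mu0 + B' x_i, Sigma)``
  with trait-specific Gaussian marker-effect priors (scaled-inverse-chi2
  hyperpriors on the effect variances) and an unstructured inverse-Wishart
  residual covariance; and
* a single-trait ordinal probit (threshold) regression per categorical
  trait, with a latent liability ``l_i = x_i' beta + e_i``, ``e_i ~ N(0,1)``
  fixed for identifiability, no intercept (the thresholds play that role),
  and strictly increasing free thresholds. Effects are sampled by the
  classic liability data-augmentation scheme; thresholds use a joint
  random-walk Metropolis step on the observed-data (liability-integrated)
  likelihood, which mixes far better than the liability-order-statistic
  update at these sample sizes.

For a selection candidate the continuous means and the latent ordinal
means are stacked into one joint multivariate normal per retained draw,
with block-diagonal covariance ``blockdiag(Sigma, I)`` — continuous traits
keep their unstructured residual covariance, latent traits are assumed
mutually independent with unit variance.

Marker covariates are centered internally (stored per chain) so that the
Gaussian intercepts and the ordinal thresholds absorb the means; candidate
genotypes are centered with the training means at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import ndtr, ndtri

__all__ = [
    "McmcSettings",
    "GaussianChain",
    "OrdinalChain",
    "PredictiveEnsemble",
    "fit_gaussian_multitrait",
    "fit_ordinal_probit",
    "category_probabilities",
    "assemble_ccmm_predictive",
]

_LIAB_CLIP = 10.0  # numeric guard for liabilities when a truncation interval underflows


@dataclass
class McmcSettings:
    """Chain length controls and the prior variance split.

    ``r2`` is the prior proportion of phenotypic variance attributed to
    markers, used to scale the weakly informative effect-variance and
    residual hyperpriors; ``df_effect`` is the prior degrees of freedom of
    the scaled-inverse-chi2 effect-variance prior.
    """

    iterations: int = 6000
    burn_in: int = 1000
    thin: int = 5
    r2: float = 0.5
    df_effect: float = 5.0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("burn_in must be >= 0 and thin >= 1")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin

    def retained(self, iteration: int) -> bool:
        return iteration >= self.burn_in and (iteration - self.burn_in) % self.thin == 0


@dataclass
class GaussianChain:
    """Retained draws of the multi-trait Gaussian marker regression."""

    mu0: np.ndarray          # (S, t)
    beta: np.ndarray         # (S, p, t)
    sigma: np.ndarray        # (S, t, t)
    effect_var: np.ndarray   # (S, t)
    x_center: np.ndarray     # (p,) training marker means
    settings: McmcSettings = field(default_factory=McmcSettings)

    @property
    def n_retained(self) -> int:
        return self.mu0.shape[0]

    @property
    def n_markers(self) -> int:
        return self.beta.shape[1]

    @property
    def n_traits(self) -> int:
        return self.mu0.shape[1]


@dataclass
class OrdinalChain:
    """Retained draws of a single-trait ordinal probit regression.

    The liability residual variance is fixed at 1; there is no intercept —
    the K-1 free thresholds act as intercepts.
    """

    beta: np.ndarray         # (S, p)
    thresholds: np.ndarray   # (S, K-1), strictly increasing per draw
    effect_var: np.ndarray   # (S,)
    x_center: np.ndarray     # (p,)
    n_categories: int = 0
    settings: McmcSettings = field(default_factory=McmcSettings)

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    @property
    def n_markers(self) -> int:
        return self.beta.shape[1]


@dataclass
class PredictiveEnsemble:
    """Per-candidate, per-draw parameters of the joint predictive normal.

    ``mu[s, c]`` stacks the continuous-trait means (first ``n_continuous``
    entries) over the latent ordinal means for candidate ``c`` at retained
    draw ``s``; ``sigma[s]`` is the shared block-diagonal covariance
    ``blockdiag(Sigma_s, I)``.
    """

    mu: np.ndarray            # (S, n_candidates, d)
    sigma: np.ndarray         # (S, d, d)
    ids: np.ndarray
    n_continuous: int
    ordinal_thresholds: list = field(default_factory=list)  # [(S, K_j - 1), ...]

    @property
    def n_retained(self) -> int:
        return self.mu.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.mu.shape[1]

    @property
    def dim(self) -> int:
        return self.mu.shape[2]

    def posterior_mean(self) -> np.ndarray:
        """Posterior-mean joint breeding values, (n_candidates, d)."""
        return self.mu.mean(axis=0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from the inverse-Wishart(df, scale) via the Bartlett construction."""
    t = scale.shape[0]
    if df <= t - 1:
        raise ValueError("inverse-Wishart degrees of freedom too small")
    A = np.zeros((t, t))
    for i in range(t):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        A[i, :i] = rng.standard_normal(i)
    L = np.linalg.cholesky(scale)
    # Sigma = L (A A')^{-1} L' = F F' with F = L A^{-T}
    F = solve_triangular(A, L.T, lower=True, trans="T").T
    return F @ F.T


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale_sum: float) -> float:
    """Draw sigma^2 from scaled-inverse-chi2: scale_sum / chi2(df)."""
    return scale_sum / rng.chisquare(df)


class _RidgeSolver:
    """Exact conditional draws of a ridge coefficient block via a one-time
    eigendecomposition of X'X: (c1 X'X + c2 I) is diagonal in the fixed
    eigenbasis, so each Gibbs update costs O(p^2)."""

    def __init__(self, X: np.ndarray):
        XtX = X.T @ X
        self.lam, self.Q = np.linalg.eigh(XtX)
        self.lam = np.clip(self.lam, 0.0, None)

    def xtx_dot(self, beta: np.ndarray) -> np.ndarray:
        return self.Q @ (self.lam * (self.Q.T @ beta))

    def draw(self, b: np.ndarray, c1: float, c2: float,
             rng: np.random.Generator) -> np.ndarray:
        """Sample from MVN with precision (c1 X'X + c2 I) and linear term b."""
        d = c1 * self.lam + c2
        qb = self.Q.T @ b
        z = rng.standard_normal(b.shape[0])
        return self.Q @ (qb / d + z / np.sqrt(d))


def fit_gaussian_multitrait(
    X, Y, settings: McmcSettings | None = None, seed=None
) -> GaussianChain:
    """Gibbs sampler for the multi-trait Gaussian marker regression.

    Parameters
    ----------
    X
        ``(n, p)`` marker dosage matrix (training lines).
    Y
        ``(n, t)`` complete continuous responses.
    settings
        Chain length and prior-scale controls.
    seed
        Integer seed or ``numpy`` Generator; fixed seed gives bit-identical
        chains.
    """
    settings = settings or McmcSettings()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if p == 0:
        raise ValueError("marker matrix has no columns")
    if Y.shape[0] != n or n < 2:
        raise ValueError("X and Y must share n >= 2 rows")
    if np.isnan(Y).any():
        raise ValueError("missing responses are not supported; phenotypes must be complete")
    t = Y.shape[1]
    rng = _as_rng(seed)

    x_center = X.mean(axis=0)
    Xc = X - x_center
    solver = _RidgeSolver(Xc)

    vy = Y.var(axis=0, ddof=1)
    if (vy <= 0).any():
        raise ValueError("every trait must have non-zero phenotypic variance")
    msx = Xc.var(axis=0, ddof=1).sum()
    msx = msx if msx > 0 else 1.0
    df0 = settings.df_effect
    # prior mode of each effect variance set so that p markers explain r2 of var(y)
    s0 = settings.r2 * vy / msx * (df0 + 2.0)
    nu0 = t + 2.0
    V0 = np.diag((1.0 - settings.r2) * vy)

    mu0 = Y.mean(axis=0).copy()
    B = np.zeros((p, t))
    Sigma = np.diag(vy * (1.0 - settings.r2))
    sig2b = np.full(t, settings.r2 * vy.mean() / msx)
    E = Y - mu0  # residuals, maintained incrementally (B = 0 initially)

    S = settings.n_retained
    out_mu0 = np.empty((S, t))
    out_beta = np.empty((S, p, t))
    out_sigma = np.empty((S, t, t))
    out_sig2b = np.empty((S, t))

    s = 0
    for it in range(settings.iterations):
        Sigma_inv = np.linalg.inv(Sigma)
        for j in range(t):
            c1 = Sigma_inv[j, j]
            b = Xc.T @ (E @ Sigma_inv[:, j]) + c1 * solver.xtx_dot(B[:, j])
            beta_new = solver.draw(b, c1, 1.0 / sig2b[j], rng)
            E[:, j] -= Xc @ (beta_new - B[:, j])
            B[:, j] = beta_new
        # intercepts (flat prior): MVN around the mean residual
        m = E.mean(axis=0) + mu0
        Ls = np.linalg.cholesky(Sigma)
        mu0_new = m + (Ls @ rng.standard_normal(t)) / np.sqrt(n)
        E += mu0 - mu0_new
        mu0 = mu0_new
        # unstructured residual covariance
        Sigma = _inv_wishart(rng, nu0 + n, V0 + E.T @ E)
        # trait-specific effect variances
        for j in range(t):
            sig2b[j] = _scaled_inv_chi2(
                rng, df0 + p, df0 * s0[j] + B[:, j] @ B[:, j]
            )
        if settings.retained(it):
            out_mu0[s] = mu0
            out_beta[s] = B
            out_sigma[s] = Sigma
            out_sig2b[s] = sig2b
            s += 1

    return GaussianChain(out_mu0, out_beta, out_sigma, out_sig2b, x_center, settings)


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Unit-variance truncated normal draws on (lo, hi] via inverse CDF."""
    a = ndtr(lo - mean)
    b = ndtr(hi - mean)
    u = a + rng.random(mean.shape[0]) * (b - a)
    draw = mean + ndtri(np.clip(u, 1e-13, 1.0 - 1e-13))
    draw = np.clip(draw, -_LIAB_CLIP, _LIAB_CLIP)
    # keep draws inside their interval even when the CDF difference underflows
    return np.minimum(np.maximum(draw, np.nextafter(lo, np.inf)), hi)


def _ordinal_loglik(eta: np.ndarray, gamma: np.ndarray, y: np.ndarray) -> float:
    """Observed-data log-likelihood sum log[Phi(g_y - eta) - Phi(g_{y-1} - eta)]."""
    edges = np.concatenate(([-np.inf], gamma, [np.inf]))
    probs = ndtr(edges[y] - eta) - ndtr(edges[y - 1] - eta)
    return float(np.log(np.clip(probs, 1e-300, None)).sum())


def _metropolis_thresholds(
    gamma: np.ndarray, eta: np.ndarray, y: np.ndarray,
    step: float, rng: np.random.Generator,
):
    """Joint random-walk Metropolis update of the ordered thresholds.

    Each proposal gamma_k* is drawn from a normal truncated to
    (gamma*_{k-1}, gamma_{k+1}) so the ordering stays strict; the
    acceptance ratio corrects for the truncation normalizers and uses the
    liability-integrated likelihood.
    """
    Km1 = gamma.shape[0]
    prop = np.empty(Km1)
    log_fwd = 0.0   # proposal normalizers, forward and reverse
    log_rev = 0.0
    for k in range(Km1):
        lo = prop[k - 1] if k > 0 else -np.inf
        hi = gamma[k + 1] if k < Km1 - 1 else np.inf
        a, b = ndtr((lo - gamma[k]) / step), ndtr((hi - gamma[k]) / step)
        u = a + rng.random() * (b - a)
        prop[k] = gamma[k] + step * ndtri(np.clip(u, 1e-13, 1 - 1e-13))
        log_fwd += np.log(max(b - a, 1e-300))
        lo_r = gamma[k - 1] if k > 0 else -np.inf
        hi_r = prop[k + 1] if k < Km1 - 1 else np.inf
        # reverse-move normalizer for proposing gamma from prop
        a_r = ndtr((lo_r - prop[k]) / step)
        b_r = ndtr((hi_r - prop[k]) / step)
        log_rev += np.log(max(b_r - a_r, 1e-300))
    log_ratio = (
        _ordinal_loglik(eta, prop, y) - _ordinal_loglik(eta, gamma, y)
        + log_rev - log_fwd
    )
    if np.log(max(rng.random(), 1e-300)) < log_ratio:
        return prop, True
    return gamma, False


def fit_ordinal_probit(
    X, y_categories, K: int | None = None,
    settings: McmcSettings | None = None, seed=None,
) -> OrdinalChain:
    """Gibbs/Metropolis sampler for the ordinal probit threshold model.

    Categories must be coded 1..K with every category observed at least
    once. Liabilities are drawn from truncated normals given the current
    effects and thresholds, effects are updated as a ridge regression on
    the liabilities with unit residual variance, and the thresholds are
    updated by a joint random-walk Metropolis step on the observed-data
    likelihood (the liabilities integrated out), keeping the ordering
    strict by construction.
    """
    settings = settings or McmcSettings()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_categories)
    n, p = X.shape
    if p == 0:
        raise ValueError("marker matrix has no columns")
    if y.shape[0] != n:
        raise ValueError("X and y must share rows")
    if not np.all(y == np.round(y)):
        raise ValueError("categories must be integers 1..K")
    y = y.astype(int)
    if K is None:
        K = int(y.max())
    if K < 2:
        raise ValueError("need at least 2 categories")
    counts = np.bincount(y, minlength=K + 1)[1:]
    if y.min() < 1 or y.max() > K:
        raise ValueError(f"categories must lie in 1..{K}")
    missing = np.flatnonzero(counts == 0) + 1
    if missing.size:
        raise ValueError(
            f"category {missing[0]} of {K} is never observed; every category "
            "must appear at least once"
        )
    rng = _as_rng(seed)

    x_center = X.mean(axis=0)
    Xc = X - x_center
    solver = _RidgeSolver(Xc)

    msx = Xc.var(axis=0, ddof=1).sum()
    msx = msx if msx > 0 else 1.0
    df0 = settings.df_effect
    s0 = settings.r2 / msx * (df0 + 2.0)  # liability variance is 1 by construction

    # thresholds start at the normal quantiles of the cumulative frequencies
    cum = np.cumsum(counts)[:-1] / n
    gamma = ndtri(np.clip(cum, 1e-6, 1 - 1e-6))
    gamma = np.maximum.accumulate(gamma + 1e-9 * np.arange(K - 1))
    beta = np.zeros(p)
    sig2b = settings.r2 / msx

    lo_edge = np.concatenate(([-np.inf], gamma))[y - 1]
    hi_edge = np.concatenate((gamma, [np.inf]))[y - 1]

    S = settings.n_retained
    out_beta = np.empty((S, p))
    out_gamma = np.empty((S, K - 1))
    out_sig2b = np.empty(S)

    mh_step = 0.5 / np.sqrt(n)  # random-walk scale for the threshold proposal
    s = 0
    for it in range(settings.iterations):
        eta = Xc @ beta
        liab = _truncated_normal(rng, eta, lo_edge, hi_edge)
        b = Xc.T @ liab
        beta = solver.draw(b, 1.0, 1.0 / sig2b, rng)
        sig2b = _scaled_inv_chi2(rng, df0 + p, df0 * s0 + beta @ beta)
        gamma, _ = _metropolis_thresholds(gamma, Xc @ beta, y, mh_step, rng)
        lo_edge = np.concatenate(([-np.inf], gamma))[y - 1]
        hi_edge = np.concatenate((gamma, [np.inf]))[y - 1]
        if settings.retained(it):
            out_beta[s] = beta
            out_gamma[s] = gamma
            out_sig2b[s] = sig2b
            s += 1

    return OrdinalChain(out_beta, out_gamma, out_sig2b, x_center, K, settings)


def category_probabilities(eta, thresholds) -> np.ndarray:
    """Ordinal category probabilities Phi(gamma_k - eta) - Phi(gamma_{k-1} - eta).

    ``eta`` may be a scalar or an array; the result appends a final axis of
    length K summing to 1.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty 1-D vector")
    if (np.diff(thresholds) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    eta = np.asarray(eta, dtype=float)
    cdf = ndtr(thresholds - eta[..., None])
    ones = np.ones(eta.shape + (1,))
    zeros = np.zeros(eta.shape + (1,))
    return np.diff(np.concatenate([zeros, cdf, ones], axis=-1), axis=-1)


def assemble_ccmm_predictive(
    gaussian_chain: GaussianChain | None,
    ordinal_chains,
    X_candidates,
    ids=None,
) -> PredictiveEnsemble:
    """Stack continuous and latent ordinal predictive blocks per retained draw.

    For candidate ``c`` at draw ``s`` the joint mean is
    ``(mu0_s + B_s' x_c, beta_1s' x_c, ..., beta_ms' x_c)`` and the joint
    covariance is ``blockdiag(Sigma_s, I_m)``. The independently fitted
    chains are paired by retained-draw index; all chains must retain the
    same number of draws and share the marker dimension.
    """
    ordinal_chains = list(ordinal_chains)
    if gaussian_chain is None and not ordinal_chains:
        raise ValueError("need at least one fitted chain")
    X_candidates = np.atleast_2d(np.asarray(X_candidates, dtype=float))
    n_cand, p = X_candidates.shape

    counts = set()
    if gaussian_chain is not None:
        counts.add(gaussian_chain.n_retained)
        if gaussian_chain.n_markers != p:
            raise ValueError("candidate markers do not match the Gaussian chain")
    for ch in ordinal_chains:
        counts.add(ch.n_retained)
        if ch.n_markers != p:
            raise ValueError("candidate markers do not match an ordinal chain")
    if len(counts) != 1:
        raise ValueError(f"chains retain different draw counts: {sorted(counts)}")
    S = counts.pop()

    t_cont = gaussian_chain.n_traits if gaussian_chain is not None else 0
    m_ord = len(ordinal_chains)
    d = t_cont + m_ord

    mu = np.empty((S, n_cand, d))
    sigma = np.zeros((S, d, d))
    if gaussian_chain is not None:
        Xc = X_candidates - gaussian_chain.x_center
        mu[:, :, :t_cont] = (
            np.einsum("np,spt->snt", Xc, gaussian_chain.beta)
            + gaussian_chain.mu0[:, None, :]
        )
        sigma[:, :t_cont, :t_cont] = gaussian_chain.sigma
    for j, ch in enumerate(ordinal_chains):
        Xo = X_candidates - ch.x_center
        mu[:, :, t_cont + j] = ch.beta @ Xo.T
        sigma[:, t_cont + j, t_cont + j] = 1.0

    if ids is None:
        ids = np.array([f"cand_{i + 1}" for i in range(n_cand)])
    return PredictiveEnsemble(
        mu, sigma, np.asarray(ids), t_cont,
        [ch.thresholds for ch in ordinal_chains],
    )
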