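"""Loss functions, posterior expected loss (PEL) and ranking.

A candidate's genetic merit is summarized by its joint predictive normal
(continuous traits stacked over latent ordinal traits). The breeder's goal
is encoded as a target normal distribution; each retained MCMC draw's
predictive normal is scored against the target with a loss on
distributions, and the posterior expected loss is the Monte-Carlo average
of those per-draw losses. Candidates are ranked from lowest to highest PEL
and the lowest fraction is selected as parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import PredictiveEnsemble

__all__ = [
    "TargetSpec",
    "SelectionResult",
    "kl_loss",
    "expected_deviation_loss",
    "posterior_expected_loss",
    "rank_and_select",
    "build_target",
]

_GOALS = ("increase", "decrease", "neutral")


@dataclass
class TargetSpec:
    """The breeder's goal as a reference normal distribution.

    ``mean``/``cov`` live on the joint (continuous + latent) scale;
    ``goals`` record the per-trait direction and, for ordinal traits,
    ``preferred_categories`` maps joint-trait index -> desired category.
    """

    mean: np.ndarray
    cov: np.ndarray
    goals: tuple = ()
    preferred_categories: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError("target covariance must be d x d")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("target covariance must be positive definite") from exc
        if self.goals:
            if len(self.goals) != d:
                raise ValueError("one goal per joint trait required")
            bad = [g for g in self.goals if g not in _GOALS]
            if bad:
                raise ValueError(f"unknown goal(s): {bad}")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class SelectionResult:
    """Per-candidate PEL, ascending rank (1 = best) and selected flag."""

    ids: np.ndarray
    pel: np.ndarray
    rank: np.ndarray
    selected: np.ndarray
    selection_fraction: float

    def selected_ids(self) -> np.ndarray:
        """Identifiers of the selected candidates, best (rank 1) first."""
        order = np.argsort(self.rank)
        return self.ids[order][self.selected[order]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "pel": self.pel,
                "rank": self.rank,
                "selected": self.selected,
            }
        ).sort_values("rank", ignore_index=True)


def _check_pd(sigma: np.ndarray, name: str) -> np.ndarray:
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} covariance must be positive definite") from exc


def kl_loss(mu_candidate, sigma_candidate, target: TargetSpec) -> float:
    """Kullback-Leibler divergence KL(target || candidate) for normals.

    Closed form: ``0.5 * [tr(Sc^-1 St) + (mc - mt)' Sc^-1 (mc - mt) - d
    + ln(det Sc / det St)]``. Zero iff the candidate's predictive normal
    equals the target; penalizes both mean displacement from the goal and
    predictive spread mismatch.
    """
    mu_c = np.atleast_1d(np.asarray(mu_candidate, dtype=float))
    d = mu_c.shape[0]
    if target.dim != d:
        raise ValueError("candidate and target dimensions differ")
    Lc = _check_pd(sigma_candidate, "candidate")
    Lt = _check_pd(target.cov, "target")
    sigma_c = np.atleast_2d(np.asarray(sigma_candidate, dtype=float))
    sol = np.linalg.solve(sigma_c, target.cov)
    diff = mu_c - target.mean
    quad = diff @ np.linalg.solve(sigma_c, diff)
    logdet_c = 2.0 * np.log(np.diag(Lc)).sum()
    logdet_t = 2.0 * np.log(np.diag(Lt)).sum()
    return 0.5 * float(np.trace(sol) + quad - d + logdet_c - logdet_t)


def expected_deviation_loss(mu_candidate, sigma_candidate, target: TargetSpec) -> float:
    """Direction-aware linear loss: goal-signed mean deviation from target.

    Sums, over non-neutral traits, ``(mt - mc)`` for increase goals and
    ``(mc - mt)`` for decrease goals, so exceeding the target in the goal
    direction contributes negatively (better than target is allowed). The
    covariance is ignored — this is the simple alternative to the KL loss.
    """
    mu_c = np.atleast_1d(np.asarray(mu_candidate, dtype=float))
    if target.dim != mu_c.shape[0]:
        raise ValueError("candidate and target dimensions differ")
    _check_pd(sigma_candidate, "candidate")
    goals = target.goals or ("increase",) * target.dim
    sign = np.array(
        [1.0 if g == "increase" else (-1.0 if g == "decrease" else 0.0) for g in goals]
    )
    return float((sign * (target.mean - mu_c)).sum())


_LOSSES = {"kl": kl_loss, "deviation": expected_deviation_loss}


def posterior_expected_loss(
    predictive: PredictiveEnsemble, target: TargetSpec, loss="kl"
) -> np.ndarray:
    """Monte-Carlo PEL per candidate: mean per-draw loss over retained draws.

    ``loss`` is ``"kl"``, ``"deviation"`` or any callable
    ``loss(mu, sigma, target) -> float`` evaluated on each draw's full
    predictive normal. Deterministic given the chains.
    """
    if predictive.n_retained < 1:
        raise ValueError("need at least one retained predictive draw")
    if target.dim != predictive.dim:
        raise ValueError("target dimension does not match the predictive")
    loss_fn = _LOSSES.get(loss, loss) if isinstance(loss, str) else loss
    if not callable(loss_fn):
        raise ValueError(f"unknown loss: {loss!r}")

    S, n, d = predictive.mu.shape
    if loss_fn is kl_loss:
        # the covariance is shared across candidates within a draw: solve once
        total = np.zeros(n)
        logdet_t = 2.0 * np.log(np.diag(_check_pd(target.cov, "target"))).sum()
        for s in range(S):
            sigma_c = predictive.sigma[s]
            Lc = _check_pd(sigma_c, "candidate")
            sol = np.linalg.solve(sigma_c, target.cov)
            diff = predictive.mu[s] - target.mean
            quad = np.einsum(
                "nd,nd->n", diff, np.linalg.solve(sigma_c, diff.T).T
            )
            logdet_c = 2.0 * np.log(np.diag(Lc)).sum()
            total += 0.5 * (np.trace(sol) + quad - d + logdet_c - logdet_t)
        return total / S
    pels = np.empty(n)
    for c in range(n):
        pels[c] = np.mean(
            [loss_fn(predictive.mu[s, c], predictive.sigma[s], target) for s in range(S)]
        )
    return pels


def rank_and_select(pels, selection_fraction: float, ids=None) -> SelectionResult:
    """Rank candidates by ascending PEL and select the lowest fraction.

    Ties are broken by candidate order (stable sort); the selected set is
    the ``ceil(fraction * n)`` lowest-PEL candidates.
    """
    pels = np.atleast_1d(np.asarray(pels, dtype=float))
    n = pels.shape[0]
    if ids is None:
        ids = np.arange(1, n + 1)
    ids = np.asarray(ids)
    if ids.shape[0] != n:
        raise ValueError("ids and pels must have equal length")
    if not 0.0 < selection_fraction <= 1.0:
        raise ValueError("selection_fraction must lie in (0, 1]")
    bad = np.flatnonzero(~np.isfinite(pels))
    if bad.size:
        raise ValueError(f"non-finite PEL for candidate {ids[bad[0]]!r}")
    order = np.argsort(pels, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    n_sel = int(np.ceil(selection_fraction * n))
    selected = rank <= n_sel
    return SelectionResult(ids, pels, rank, selected, selection_fraction)


def build_target(
    predictive: PredictiveEnsemble,
    goals,
    preferred_categories: dict | None = None,
    margin: float = 1.0,
    cov_scale: float = 1.0,
) -> TargetSpec:
    """Default target construction from the candidates' own predictive.

    Continuous traits take the goal-direction extreme of the candidates'
    posterior-mean breeding values (max for increase, min for decrease,
    pool mean for neutral). Each ordinal trait's target latent mean sits
    `margin` beyond the threshold bounding its preferred category (top
    threshold + margin for the last category, bottom threshold - margin
    for the first, the interval midpoint otherwise), concentrating target
    mass on that category under the unit latent variance. The target
    covariance is identity scaled by `cov_scale`.
    """
    goals = tuple(goals)
    if len(goals) != predictive.dim:
        raise ValueError(
            f"need a goal for every joint trait ({predictive.dim}), got {len(goals)}"
        )
    bad = [g for g in goals if g not in _GOALS]
    if bad:
        raise ValueError(f"unknown goal(s): {bad}")
    preferred_categories = dict(preferred_categories or {})

    post = predictive.posterior_mean()
    mean = np.empty(predictive.dim)
    t_cont = predictive.n_continuous
    for j in range(t_cont):
        if goals[j] == "increase":
            mean[j] = post[:, j].max()
        elif goals[j] == "decrease":
            mean[j] = post[:, j].min()
        else:
            mean[j] = post[:, j].mean()
    for k, thr in enumerate(predictive.ordinal_thresholds):
        j = t_cont + k
        gam = np.asarray(thr).mean(axis=0)  # posterior-mean thresholds
        n_cat = gam.shape[0] + 1
        pref = preferred_categories.get(j)
        if pref is None:
            pref = n_cat if goals[j] != "decrease" else 1
        if not 1 <= pref <= n_cat:
            raise ValueError(f"preferred category {pref} outside 1..{n_cat}")
        if pref == n_cat:
            mean[j] = gam[-1] + margin
        elif pref == 1:
            mean[j] = gam[0] - margin
        else:
            mean[j] = 0.5 * (gam[pref - 2] + gam[pref - 1])
    cov = np.eye(predictive.dim) * cov_scale
    return TargetSpec(mean, cov, goals, preferred_categories)


def category_mass_at_target(target_mean: float, thresholds, category: int) -> float:
    """P(category) of a unit-variance liability centered at the target mean."""
    thresholds = np.asarray(thresholds, dtype=float)
    from scipy.special import ndtr

    edges = np.concatenate(([-np.inf], thresholds, [np.inf]))
    return float(
        ndtr(edges[category] - target_mean) - ndtr(edges[category - 1] - target_mean)
    )
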