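"""Pleiotropic trait architecture: effects, genetic values, heritability.

Every locus carries an additive effect on every trait (full pleiotropy);
the per-locus effect vectors are i.i.d. multivariate normal, so the
expected cross-trait correlation of genetic values equals the correlation
implied by the effect covariance. Phenotypes add independent normal noise
calibrated once, in the founder generation, to hit a target narrow-sense
heritability h2 = Var_A / (Var_A + sigma_e^2). Ordinal traits are the
discretized version of a continuous liability against a strictly
increasing threshold vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popsim import Population, make_founders

__all__ = [
    "founder_correlation_experiment",
    "TraitArchitecture",
    "PhenotypeTable",
    "DEFAULT_GENETIC_CORR",
    "CM_CATEGORY_PROPORTIONS",
    "CCMM_CATEGORY_PROPORTIONS",
    "sample_effects",
    "genetic_values",
    "calibrate_environment",
    "phenotype",
    "discretize",
    "thresholds_from_proportions",
]

#: Target founder-generation genetic correlations for trait pairs
#: (1,2), (2,3) and (1,3) used throughout the simulation study.
DEFAULT_GENETIC_CORR = np.array(
    [
        [1.00, -0.37, -0.02],
        [-0.37, 1.00, 0.34],
        [-0.02, 0.34, 1.00],
    ]
)

#: Founder category proportions for the all-ordinal (CM) scenario,
#: one row of (P[cat1], P[cat2], P[cat3]) per trait.
CM_CATEGORY_PROPORTIONS = (
    (0.49, 0.34, 0.17),
    (0.49, 0.23, 0.28),
    (0.14, 0.36, 0.50),
)

#: Founder category proportions of the single ordinal trait (trait 3) in
#: the continuous-categorical mixture (CCMM) scenario.
CCMM_CATEGORY_PROPORTIONS = (0.49, 0.19, 0.32)


@dataclass
class TraitArchitecture:
    """Ground truth of the simulated traits.

    ``effects`` has one row per locus and one column per trait;
    ``kinds`` marks each trait ``"continuous"`` or ``"ordinal"``;
    ``thresholds`` maps ordinal trait index -> strictly increasing
    liability cut points (frozen after founder calibration).
    """

    effects: np.ndarray
    genetic_cov: np.ndarray
    h2: np.ndarray
    env_sd: np.ndarray
    kinds: tuple
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        self.h2 = np.asarray(self.h2, dtype=float)
        self.env_sd = np.asarray(self.env_sd, dtype=float)
        t = self.effects.shape[1]
        if len(self.kinds) != t or self.h2.shape[0] != t or self.env_sd.shape[0] != t:
            raise ValueError("per-trait fields must all have one entry per trait")
        if ((self.h2 <= 0) | (self.h2 > 1)).any():
            raise ValueError("h2 must lie in (0, 1]")
        if (self.env_sd < 0).any():
            raise ValueError("environmental SDs must be non-negative")
        for j, gam in self.thresholds.items():
            gam = np.asarray(gam, dtype=float)
            if gam.ndim != 1 or (np.diff(gam) <= 0).any():
                raise ValueError(f"thresholds for trait {j} must be strictly increasing")
            self.thresholds[j] = gam

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]

    @property
    def continuous_traits(self) -> list:
        return [j for j, k in enumerate(self.kinds) if k == "continuous"]

    @property
    def ordinal_traits(self) -> list:
        return [j for j, k in enumerate(self.kinds) if k == "ordinal"]


@dataclass
class PhenotypeTable:
    """Observed phenotypes plus the simulation's true genetic values.

    ``observed`` holds real values for continuous traits and 1-based
    category indices for ordinal traits; ``true_genetic`` is retained for
    monitoring only and is never shown to the fitting machinery.
    """

    ids: np.ndarray
    observed: np.ndarray
    kinds: tuple
    true_genetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.observed = np.atleast_2d(np.asarray(self.observed, dtype=float))
        for j, kind in enumerate(self.kinds):
            if kind == "ordinal":
                col = self.observed[:, j]
                if not np.all(col == np.round(col)) or col.min() < 1:
                    raise ValueError(
                        f"ordinal trait {j} must hold integer categories >= 1"
                    )


def sample_effects(n_loci: int, genetic_covariance, seed=None) -> np.ndarray:
    """Draw per-locus pleiotropic effect vectors, i.i.d. MVN(0, covariance).

    The covariance must be symmetric positive semi-definite. Because each
    locus affects every trait, the expected genetic-value correlation
    matrix across lines equals the correlation form of this covariance.
    """
    cov = np.atleast_2d(np.asarray(genetic_covariance, dtype=float))
    if cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T):
        raise ValueError("genetic covariance must be square and symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("genetic covariance must be positive semi-definite")
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_normal(
        np.zeros(cov.shape[0]), cov, size=n_loci, method="svd"
    )


def genetic_values(population: Population, effects: np.ndarray) -> np.ndarray:
    """True additive genetic values: raw dosage matrix times effect matrix."""
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    if population.n_loci != effects.shape[0]:
        raise ValueError(
            f"effect matrix has {effects.shape[0]} loci but population has "
            f"{population.n_loci}"
        )
    return population.genotypes.astype(float) @ effects


def calibrate_environment(gvalues: np.ndarray, target_h2) -> np.ndarray:
    """Environmental SDs making Var_A / (Var_A + sigma_e^2) hit `target_h2`.

    Uses the additive variance realized in the reference (founder)
    population: sigma_e = sqrt(Var_A * (1 - h2) / h2) per trait.
    """
    gvalues = np.atleast_2d(np.asarray(gvalues, dtype=float))
    h2 = np.broadcast_to(np.asarray(target_h2, dtype=float), (gvalues.shape[1],))
    if ((h2 <= 0) | (h2 > 1)).any():
        raise ValueError("target h2 must lie in (0, 1]")
    var_a = gvalues.var(axis=0, ddof=1)
    if (var_a <= 0).any():
        raise ValueError("genetic values have zero variance; cannot calibrate h2")
    return np.sqrt(var_a * (1.0 - h2) / h2)


def phenotype(gvalues: np.ndarray, env_sd, seed=None) -> np.ndarray:
    """Add independent per-trait normal environmental noise to genetic values."""
    gvalues = np.atleast_2d(np.asarray(gvalues, dtype=float))
    env_sd = np.broadcast_to(np.asarray(env_sd, dtype=float), (gvalues.shape[1],))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return gvalues + rng.standard_normal(gvalues.shape) * env_sd


def discretize(values, thresholds) -> np.ndarray:
    """Map continuous values to 1-based ordered categories.

    With cut points gamma_1 < ... < gamma_{K-1}, category k is assigned when
    the value falls in the interval (gamma_{k-1}, gamma_k], with gamma_0 =
    -inf and gamma_K = +inf; a value exactly on a cut point takes the lower
    category.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty 1-D vector")
    if (np.diff(thresholds) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    values = np.asarray(values, dtype=float)
    return np.searchsorted(thresholds, values, side="left") + 1


def thresholds_from_proportions(values, proportions) -> np.ndarray:
    """Liability cut points reproducing the requested category proportions.

    Places K-1 thresholds at the cumulative-proportion sample quantiles of
    `values`, so that ``discretize(values, thresholds)`` yields category
    shares matching `proportions` up to integer rounding.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.ndim != 1 or proportions.size < 2:
        raise ValueError("need at least two category proportions")
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("category proportions must sum to 1")
    cum = np.cumsum(proportions)[:-1]
    thr = np.quantile(np.asarray(values, dtype=float), cum)
    if (np.diff(thr) <= 0).any():
        raise ValueError("quantile thresholds are not strictly increasing (too many ties)")
    return thr


def founder_correlation_experiment(
    n_lines: int = 2000,
    n_loci: int = 8000,
    n_generations: int = 200,
    allele_freq: float = 0.5,
    n_seeds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Realized founder genetic-value correlations, averaged over seeds.

    For each independent seed: simulate a drifted founder population,
    sample pleiotropic effects targeting :data:`DEFAULT_GENETIC_CORR`,
    compute true genetic values, and record the Pearson correlations for
    trait pairs (1,2), (2,3), (1,3). Returns the across-seed mean of the
    three correlations; at the default full scale these converge to the
    targets (-0.37, 0.34, -0.02) up to Monte-Carlo error.
    """
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    corrs = np.empty((n_seeds, 3))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pop = make_founders(n_lines, n_loci, allele_freq, n_generations, rng)
        effects = sample_effects(n_loci, DEFAULT_GENETIC_CORR, rng)
        gv = genetic_values(pop, effects)
        c = np.corrcoef(gv.T)
        corrs[i] = (c[0, 1], c[1, 2], c[0, 2])
    return corrs.mean(axis=0)
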