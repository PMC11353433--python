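"""Recurrent genomic selection program: cycle loop, monitoring, analysis.

Each cycle phenotypes a random 70% training split, fits the multi-trait
Gaussian model on continuous traits and an independent probit threshold
model per ordinal trait, assembles the joint predictive for the remaining
candidate pool, ranks candidates by posterior expected loss against the
breeder's target, selects the lowest-PEL fraction, and random-mates the
selected parents into the next cycle's doubled-haploid population of
constant size. Population means of true genetic values, realized
heritabilities and ordinal category proportions are monitored per cycle,
and whole programs are replicated Monte-Carlo style from a master seed.
Trend slopes and Kruskal-Wallis / Mann-Whitney-Bonferroni comparisons
across cycles summarize the monitored series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import traitsim
from .bayes import McmcSettings, OrdinalChain, assemble_ccmm_predictive, \
    fit_gaussian_multitrait, fit_ordinal_probit
from .decision import build_target, posterior_expected_loss, rank_and_select
from .popsim import Population, make_dh_offspring, make_founders
from .traitsim import TraitArchitecture, calibrate_environment, discretize, \
    genetic_values, phenotype, sample_effects, thresholds_from_proportions

__all__ = [
    "ProgramConfig",
    "CycleRecord",
    "PRESETS",
    "preset",
    "setup_architecture",
    "run_cycle",
    "run_program",
    "trend_slopes",
    "nonparametric_tests",
    "TestReport",
]


@dataclass
class ProgramConfig:
    """Configuration of a recurrent-selection simulation experiment."""

    scenario: str = "CCMM"              # "CM" (all ordinal) or "CCMM" (2 cont + 1 ord)
    n_cycles: int = 10
    n_lines: int = 2000
    n_loci: int = 8000
    founder_generations: int = 200
    allele_freq: float = 0.5
    h2: float = 0.6
    train_fraction: float = 0.7
    selection_fraction: float = 0.3
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    loss: str = "kl"
    margin: float = 1.0
    selection_method: str = "pel"       # "pel" | "random" | "truth"
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("CM", "CCMM"):
            raise ValueError("scenario must be 'CM' or 'CCMM'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must lie in (0, 1]")
        for name in ("n_cycles", "n_lines", "n_loci", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.selection_method not in ("pel", "random", "truth"):
            raise ValueError("selection_method must be 'pel', 'random' or 'truth'")

    @property
    def trait_kinds(self) -> tuple:
        if self.scenario == "CM":
            return ("ordinal", "ordinal", "ordinal")
        return ("continuous", "continuous", "ordinal")

    @property
    def category_proportions(self) -> dict:
        if self.scenario == "CM":
            return {j: traitsim.CM_CATEGORY_PROPORTIONS[j] for j in range(3)}
        return {2: traitsim.CCMM_CATEGORY_PROPORTIONS}

    @property
    def goals(self) -> tuple:
        # preference for the third category of every ordinal trait, and
        # increasing genetic values for every continuous trait
        return ("increase",) * 3

    def replace(self, **kw) -> "ProgramConfig":
        return dataclasses.replace(self, **kw)


#: ``full-scale`` is the headline experiment scale; ``desk-test`` is the
#: reduced scale used by the test suite (small populations, short chains).
PRESETS = {
    "full-scale": ProgramConfig(),
    "desk-test": ProgramConfig(
        n_cycles=5,
        n_lines=300,
        n_loci=500,
        founder_generations=100,
        n_replicates=5,
        mcmc=McmcSettings(iterations=600, burn_in=200, thin=4),
    ),
}


def preset(name: str, **overrides) -> ProgramConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name].replace(**overrides)


@dataclass
class CycleRecord:
    """Monitoring statistics of one cycle's population (before selection)."""

    replicate: int
    cycle: int
    mean_genetic_value: np.ndarray         # per trait
    realized_h2: np.ndarray                # per trait (Var_A / (Var_A + sd_e^2))
    category_proportions: dict             # ordinal trait index -> (K,) shares
    selected_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        for j, props in self.category_proportions.items():
            if not np.isclose(np.sum(props), 1.0):
                raise ValueError(f"category proportions for trait {j} must sum to 1")

    def to_rows(self) -> list:
        rows = []
        for j, g in enumerate(self.mean_genetic_value):
            rows.append(
                dict(replicate=self.replicate, cycle=self.cycle, trait=j + 1,
                     category=np.nan, quantity="mean_gv", value=float(g))
            )
            rows.append(
                dict(replicate=self.replicate, cycle=self.cycle, trait=j + 1,
                     category=np.nan, quantity="h2", value=float(self.realized_h2[j]))
            )
        for j, props in self.category_proportions.items():
            for k, p in enumerate(props):
                rows.append(
                    dict(replicate=self.replicate, cycle=self.cycle, trait=j + 1,
                         category=k + 1, quantity="category_prop", value=float(p))
                )
        return rows


def setup_architecture(
    founders: Population, config: ProgramConfig, rng: np.random.Generator
) -> TraitArchitecture:
    """Sample the pleiotropic truth and calibrate it on the founders.

    Effects are drawn from the zero-mean MVN whose correlation structure
    targets the founder genetic correlations (-0.37, 0.34, -0.02);
    environmental SDs are fixed so the founder narrow-sense heritability
    equals ``config.h2``; ordinal thresholds are placed at founder
    liability-phenotype quantiles reproducing the scenario's stated
    category proportions, then frozen for all later cycles.
    """
    effects = sample_effects(config.n_loci, traitsim.DEFAULT_GENETIC_CORR, rng)
    gv = genetic_values(founders, effects)
    env_sd = calibrate_environment(gv, config.h2)
    liab = phenotype(gv, env_sd, rng)
    thresholds = {}
    for j, props in config.category_proportions.items():
        thresholds[j] = thresholds_from_proportions(liab[:, j], props)
    return TraitArchitecture(
        effects=effects,
        genetic_cov=traitsim.DEFAULT_GENETIC_CORR,
        h2=np.full(3, config.h2),
        env_sd=env_sd,
        kinds=config.trait_kinds,
        thresholds=thresholds,
    )


def _monitor(
    replicate: int, cycle: int, gv: np.ndarray, pheno: np.ndarray,
    arch: TraitArchitecture,
) -> CycleRecord:
    var_a = gv.var(axis=0, ddof=1)
    h2 = var_a / (var_a + arch.env_sd**2)
    props = {}
    for j in arch.ordinal_traits:
        K = arch.thresholds[j].shape[0] + 1
        cats = discretize(pheno[:, j], arch.thresholds[j])
        props[j] = np.bincount(cats, minlength=K + 1)[1:] / cats.shape[0]
    return CycleRecord(replicate, cycle, gv.mean(axis=0), h2, props)


def _fit_ordinal_with_recode(X, cats, settings, rng):
    """Fit the threshold model after recoding to the observed category set.

    Selection can drive extreme categories extinct in a training split; the
    sampler requires every category observed, so categories are relabeled
    to the contiguous observed set. If fewer than two categories remain the
    trait is uninformative for this cycle and a flat (zero-effect,
    zero-threshold) chain is returned.
    """
    observed = np.unique(cats)
    y = np.searchsorted(observed, cats) + 1
    k_eff = observed.shape[0]
    if k_eff < 2:
        S = settings.n_retained
        p = X.shape[1]
        return OrdinalChain(
            np.zeros((S, p)), np.zeros((S, 1)), np.zeros(S),
            np.asarray(X, dtype=float).mean(axis=0), 2, settings,
        )
    seed = int(rng.integers(2**31))
    return fit_ordinal_probit(X, y, k_eff, settings, seed)


def run_cycle(
    population: Population,
    arch: TraitArchitecture,
    config: ProgramConfig,
    rng: np.random.Generator,
    replicate: int = 1,
    cycle: int = 1,
):
    """One selection cycle; returns the next population and this cycle's record.

    The population is monitored, split 70/30 into training and candidates
    (re-randomized each cycle), phenotyped, modeled, and the lowest-PEL
    fraction of the candidate pool is selected and random-mated into the
    next cycle's doubled-haploid population.
    """
    n = population.n_lines
    if n < 10:
        raise ValueError("population too small to run a selection cycle")
    gv = genetic_values(population, arch.effects)
    pheno = phenotype(gv, arch.env_sd, rng)
    record = _monitor(replicate, cycle, gv, pheno, arch)

    perm = rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    train_idx, cand_idx = perm[:n_train], perm[n_train:]
    cand_ids = population.ids[cand_idx]
    n_sel = int(np.ceil(config.selection_fraction * cand_idx.shape[0]))

    if config.selection_method == "random":
        selected = rng.choice(cand_ids, size=n_sel, replace=False)
    elif config.selection_method == "truth":
        score = -gv[cand_idx].sum(axis=1)  # all goals are "increase"
        order = np.argsort(score, kind="stable")
        selected = cand_ids[order[:n_sel]]
    else:
        X_train = population.genotypes[train_idx].astype(float)
        X_cand = population.genotypes[cand_idx].astype(float)
        cont = arch.continuous_traits
        gaussian = None
        if cont:
            seed = int(rng.integers(2**31))
            gaussian = fit_gaussian_multitrait(
                X_train, pheno[train_idx][:, cont], config.mcmc, seed
            )
        ordinal_chains = []
        for j in arch.ordinal_traits:
            cats = discretize(pheno[train_idx, j], arch.thresholds[j])
            ordinal_chains.append(
                _fit_ordinal_with_recode(X_train, cats, config.mcmc, rng)
            )
        predictive = assemble_ccmm_predictive(gaussian, ordinal_chains, X_cand, cand_ids)
        joint_goals = tuple(config.goals[j] for j in cont) + tuple(
            config.goals[j] for j in arch.ordinal_traits
        )
        target = build_target(predictive, joint_goals, margin=config.margin)
        pels = posterior_expected_loss(predictive, target, config.loss)
        result = rank_and_select(pels, config.selection_fraction, cand_ids)
        selected = result.selected_ids()

    record.selected_ids = np.asarray(selected)
    if record.selected_ids.shape[0] < 2:
        raise RuntimeError(
            f"cycle {cycle}: fewer than 2 parents selected; cannot continue"
        )
    next_pop = make_dh_offspring(
        population, record.selected_ids, config.n_lines, rng,
        generation=f"C{cycle + 1}",
    )
    return next_pop, record


def _run_replicate(config: ProgramConfig, replicate: int, seed_seq) -> list:
    rng = np.random.default_rng(seed_seq)
    founders = make_founders(
        config.n_lines, config.n_loci, config.allele_freq,
        config.founder_generations, rng,
    )
    arch = setup_architecture(founders, config, rng)
    population = founders
    records = []
    for cycle in range(1, config.n_cycles + 1):
        population, record = run_cycle(
            population, arch, config, rng, replicate=replicate, cycle=cycle
        )
        records.append(record)
    return records


def run_program(config: ProgramConfig) -> pd.DataFrame:
    """Run all Monte-Carlo replicates; returns a tidy long-format table.

    Columns: ``replicate``, ``cycle``, ``trait`` (1-based), ``category``
    (NaN for continuous quantities), ``quantity`` (``mean_gv``, ``h2`` or
    ``category_prop``) and ``value``. Replicates draw independent streams
    from the master seed via ``SeedSequence.spawn``; a failing replicate
    aborts the run with its replicate index in the error message.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows: list = []
    for r, child in enumerate(children, start=1):
        try:
            records = _run_replicate(config, r, child)
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        for record in records:
            rows.extend(record.to_rows())
    return pd.DataFrame(rows)


def trend_slopes(results: pd.DataFrame) -> pd.DataFrame:
    """Least-squares linear trends of every monitored quantity against cycle.

    Per replicate: the fitted slope, the percent change per cycle relative
    to that replicate's cycle-1 level, and the total percent change
    (last cycle - cycle 1, relative to cycle 1). Pooled rows (replicate 0)
    average the per-replicate statistics. A cycle-1 level of exactly zero
    leaves the percent columns NaN.
    """
    if results["cycle"].nunique() < 2:
        raise ValueError("trend estimation needs at least 2 cycles")
    rows = []
    for (quantity, trait, category), g in results.groupby(
        ["quantity", "trait", "category"], dropna=False
    ):
        group_rows = []
        for rep, gr in g.groupby("replicate"):
            gr = gr.sort_values("cycle")
            x = gr["cycle"].to_numpy(dtype=float)
            v = gr["value"].to_numpy(dtype=float)
            if np.ptp(v) == 0.0:
                slope = 0.0
            else:
                slope = float(np.polyfit(x, v, 1)[0])
            base = v[0]
            pct = slope / base * 100.0 if base != 0 else np.nan
            total = (v[-1] - v[0]) / base * 100.0 if base != 0 else np.nan
            group_rows.append(
                dict(quantity=quantity, trait=trait, category=category,
                     replicate=rep, slope=slope, pct_per_cycle=pct,
                     total_pct_change=total)
            )
        pcts = [r["pct_per_cycle"] for r in group_rows if not np.isnan(r["pct_per_cycle"])]
        totals = [
            r["total_pct_change"] for r in group_rows
            if not np.isnan(r["total_pct_change"])
        ]
        pooled = dict(
            quantity=quantity, trait=trait, category=category, replicate=0,
            slope=float(np.mean([r["slope"] for r in group_rows])),
            pct_per_cycle=float(np.mean(pcts)) if pcts else np.nan,
            total_pct_change=float(np.mean(totals)) if totals else np.nan,
        )
        rows.extend(group_rows)
        rows.append(pooled)
    return pd.DataFrame(rows)


@dataclass
class TestReport:
    """Kruskal-Wallis p-value and the Bonferroni-corrected pairwise matrix."""

    quantity: str
    trait: int
    category: int | None
    kruskal_p: float
    pairwise: pd.DataFrame  # "S"/"NS" strings, rows cycle 2..C vs columns 1..C-1
    alpha: float

    @property
    def significant(self) -> bool:
        return self.kruskal_p < self.alpha


def nonparametric_tests(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Across-cycle location tests for every monitored quantity.

    Kruskal-Wallis across all cycles (replicate values as samples) plus all
    pairwise two-sided Mann-Whitney U tests with Bonferroni correction over
    the C(C,2) comparisons, reported as an S/NS lower-triangle matrix.
    Returns a dict keyed by ``(quantity, trait, category)``.
    """
    cycles = np.sort(results["cycle"].unique())
    if cycles.shape[0] < 2:
        raise ValueError("need at least 2 cycles to compare")
    if results.groupby("cycle")["replicate"].nunique().min() < 2:
        raise ValueError("need at least 2 replicates per cycle")
    n_pairs = cycles.shape[0] * (cycles.shape[0] - 1) // 2
    reports: dict = {}
    for (quantity, trait, category), g in results.groupby(
        ["quantity", "trait", "category"], dropna=False
    ):
        samples = [g.loc[g["cycle"] == c, "value"].to_numpy() for c in cycles]
        try:
            kw_p = float(stats.kruskal(*samples).pvalue)
        except ValueError:  # all values identical
            kw_p = 1.0
        mat = pd.DataFrame(
            "", index=[f"Cycle {c}" for c in cycles[1:]],
            columns=[f"Cycle {c}" for c in cycles[:-1]],
        )
        for i, ci in enumerate(cycles):
            for jdx in range(i + 1, cycles.shape[0]):
                cj = cycles[jdx]
                a, b = samples[i], samples[jdx]
                if np.ptp(np.concatenate([a, b])) == 0.0:
                    p = 1.0
                else:
                    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                p_adj = min(1.0, p * n_pairs)
                mat.loc[f"Cycle {cj}", f"Cycle {ci}"] = "S" if p_adj < alpha else "NS"
        cat_key = None if pd.isna(category) else int(category)
        reports[(quantity, int(trait), cat_key)] = TestReport(
            quantity, int(trait), cat_key, kw_p, mat, alpha
        )
    return reports
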