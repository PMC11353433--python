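"""Delimited-text formats, run configuration, fixtures and report helpers.

Canonical formats are plain CSV: a genotype matrix has a header of marker
names and a leading ``id`` column with integer dosages in {0, 1, 2}; a
phenotype table has a leading ``id`` column and one column per trait
(real-valued for continuous traits, 1-based integer categories for
ordinal ones). MCMC chains persist as long-format CSV (draw, parameter,
value) plus a small YAML sidecar, so selections can be recomputed without
refitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats

from . import traitsim
from .bayes import GaussianChain, McmcSettings, OrdinalChain
from .decision import SelectionResult
from .popsim import DIPLOID, DOUBLED_HAPLOID, Population, make_founders
from .traitsim import PhenotypeTable, discretize, genetic_values, phenotype

__all__ = [
    "TraitMeta",
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "quartile_categorize",
    "ranking_discrepancy",
    "make_fixtures",
    "save_chains",
    "load_chains",
]

_FLOAT_FMT = "%.8g"


@dataclass
class TraitMeta:
    """Name, kind and (for ordinal traits) category count, goal and preference."""

    name: str
    kind: str = "continuous"            # "continuous" | "ordinal"
    n_categories: int | None = None
    goal: str = "increase"              # "increase" | "decrease" | "neutral"
    preferred_category: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(f"ordinal trait {self.name!r} needs n_categories >= 2")
            if self.preferred_category is None:
                self.preferred_category = (
                    self.n_categories if self.goal != "decrease" else 1
                )
            if not 1 <= self.preferred_category <= self.n_categories:
                raise ValueError(
                    f"preferred category of {self.name!r} outside 1..{self.n_categories}"
                )


@dataclass
class RunConfig:
    """Everything needed to reproduce a fit/select run from files."""

    scenario: str = "CCMM"
    traits: list = field(default_factory=list)   # list[TraitMeta]
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    loss: str = "kl"
    margin: float = 1.0
    selection_fraction: float = 0.3
    seed: int = 0
    h2: float = 0.6
    preset: str | None = None

    def __post_init__(self) -> None:
        self.traits = [
            t if isinstance(t, TraitMeta) else TraitMeta(**t) for t in self.traits
        ]

    @property
    def continuous(self) -> list:
        return [t for t in self.traits if t.kind == "continuous"]

    @property
    def ordinal(self) -> list:
        return [t for t in self.traits if t.kind == "ordinal"]

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "mcmc" in data and isinstance(data["mcmc"], dict):
            data["mcmc"] = McmcSettings(**data["mcmc"])
        return cls(**data)


# ---------------------------------------------------------------------------
# genotype / phenotype tables


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus data columns")
    return df


def write_genotypes(population: Population, path) -> None:
    df = pd.DataFrame(
        population.genotypes,
        columns=[f"M{m + 1}" for m in range(population.n_loci)],
    )
    df.insert(0, "id", population.ids)
    df.to_csv(path, index=False)


def read_genotypes(path, generation: str = "F0") -> Population:
    """Parse a dosage matrix; errors name the offending row and column."""
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).to_numpy()
    data = df.iloc[:, 1:]
    values = data.to_numpy()
    numeric = pd.to_numeric(values.ravel(), errors="coerce").reshape(values.shape)
    bad = ~np.isin(numeric, (0.0, 1.0, 2.0)) | np.isnan(numeric)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid dosage {values[r, c]!r} at line {r + 2}, "
            f"column {data.columns[c]!r} (must be 0, 1 or 2)"
        )
    geno = numeric.astype(np.uint8)
    ploidy = DIPLOID if (geno == 1).any() else DOUBLED_HAPLOID
    return Population(geno, ids=ids, generation=generation, ploidy_state=ploidy)


def write_phenotypes(table: PhenotypeTable, path, names=None) -> None:
    names = names or [f"trait{j + 1}" for j in range(table.observed.shape[1])]
    df = pd.DataFrame({"id": table.ids})
    for j, name in enumerate(names):
        col = table.observed[:, j]
        df[name] = col.astype(int) if table.kinds[j] == "ordinal" else col
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_phenotypes(path, traits) -> PhenotypeTable:
    """Parse a phenotype table against the trait metadata (order matters)."""
    traits = [t if isinstance(t, TraitMeta) else TraitMeta(**t) for t in traits]
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).to_numpy()
    missing = [t.name for t in traits if t.name not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trait columns {missing}")
    obs = np.empty((df.shape[0], len(traits)))
    for j, t in enumerate(traits):
        col = pd.to_numeric(df[t.name], errors="coerce").to_numpy()
        if np.isnan(col).any():
            r = int(np.flatnonzero(np.isnan(col))[0])
            raise ValueError(
                f"{path}: non-numeric value at line {r + 2}, column {t.name!r}"
            )
        if t.kind == "ordinal":
            if not np.all(col == np.round(col)):
                r = int(np.flatnonzero(col != np.round(col))[0])
                raise ValueError(
                    f"{path}: non-integer category at line {r + 2}, column {t.name!r}"
                )
            if col.min() < 1 or col.max() > t.n_categories:
                raise ValueError(
                    f"{path}: categories of {t.name!r} outside 1..{t.n_categories}"
                )
        obs[:, j] = col
    return PhenotypeTable(ids, obs, tuple(t.kind for t in traits))


# ---------------------------------------------------------------------------
# quartile categorization and ranking comparison (real-data-style workflow)


def quartile_categorize(values, n_categories: int = 4, reverse: bool = False) -> np.ndarray:
    """Cut a continuous trait into ordered categories at sample quantiles.

    Bins are lower-open/upper-closed at type-7 sample quantiles. With
    ``reverse=True`` the highest raw values map to category 1 — the
    severity orientation, where the top category is the most desirable
    (e.g. least diseased) group.
    """
    values = np.asarray(values, dtype=float)
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if np.unique(values).size < n_categories:
        raise ValueError("too few distinct values to form the requested categories")
    cuts = np.quantile(values, np.arange(1, n_categories) / n_categories)
    if (np.diff(cuts) <= 0).any():
        raise ValueError("tied quantiles: too many duplicate values to form categories")
    cats = np.searchsorted(cuts, values, side="left") + 1
    if reverse:
        cats = n_categories + 1 - cats
    return cats


def ranking_discrepancy(
    result_all: SelectionResult, result_subset: SelectionResult, k: int
) -> dict:
    """Compare two candidate rankings (e.g. all traits vs continuous-only).

    Reports the size and membership of the top-``k`` overlap, per-line rank
    shifts, and the Spearman correlation between the two full orderings.
    """
    ids_a = np.asarray(result_all.ids)
    ids_b = np.asarray(result_subset.ids)
    if set(ids_a.tolist()) != set(ids_b.tolist()):
        raise ValueError("the two results rank different candidate sets")
    rank_b = dict(zip(ids_b.tolist(), result_subset.rank.tolist()))
    shifts = pd.DataFrame(
        {
            "id": ids_a,
            "rank_all": result_all.rank,
            "rank_subset": [rank_b[i] for i in ids_a.tolist()],
        }
    )
    shifts["shift"] = shifts["rank_subset"] - shifts["rank_all"]
    top_a = set(ids_a[result_all.rank <= k].tolist())
    top_b = set(ids_b[result_subset.rank <= k].tolist())
    overlap = sorted(top_a & top_b)
    rho = float(
        _sstats.spearmanr(shifts["rank_all"], shifts["rank_subset"]).statistic
    )
    return {
        "k": k,
        "top_k_overlap": len(overlap),
        "overlap_ids": overlap,
        "rank_shifts": shifts.sort_values("rank_all", ignore_index=True),
        "spearman": rho,
    }


# ---------------------------------------------------------------------------
# fixture bundles


#: Fixed 5-trait correlation used by the wheat-style fixture: three yield
#: environments (moderately positively correlated) and two synthetic rust
#: severities (negatively correlated with yield).
_WHEAT_STYLE_CORR = np.array(
    [
        [1.00, 0.45, 0.35, -0.25, -0.20],
        [0.45, 1.00, 0.40, -0.20, -0.25],
        [0.35, 0.40, 1.00, -0.15, -0.20],
        [-0.25, -0.20, -0.15, 1.00, 0.30],
        [-0.20, -0.25, -0.20, 0.30, 1.00],
    ]
)

_FIXTURE_PRESETS = ("cm", "ccmm", "wheat-style")


def make_fixtures(preset: str, seed: int, outdir) -> dict:
    """Write a small seeded genotype/phenotype/config bundle to `outdir`.

    Presets: ``cm`` (3 three-category ordinal traits), ``ccmm`` (2
    continuous + 1 three-category ordinal trait) — both 120 training + 30
    candidate lines on 300 loci with the simulation study's correlation
    targets — and ``wheat-style``, a synthetic stand-in shaped like the
    wheat example (300 training + 50 candidate lines, 3 continuous yield
    traits + 2 four-category severity traits cut at sample quartiles with
    category 1 = worst). Same seed, same bytes.
    """
    if preset not in _FIXTURE_PRESETS:
        raise KeyError(f"unknown fixture preset {preset!r}; choose from {_FIXTURE_PRESETS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if preset == "wheat-style":
        n_train, n_cand, n_loci = 300, 50, 400
        corr = _WHEAT_STYLE_CORR
        traits = [
            TraitMeta("GY_env1"), TraitMeta("GY_env2"), TraitMeta("GY_env3"),
            TraitMeta("SR_sev", "ordinal", 4, "increase", 4),
            TraitMeta("YR_sev", "ordinal", 4, "increase", 4),
        ]
        scenario = "CCMM"
    else:
        n_train, n_cand, n_loci = 120, 30, 300
        corr = traitsim.DEFAULT_GENETIC_CORR
        if preset == "cm":
            traits = [
                TraitMeta(f"trait{j + 1}", "ordinal", 3, "increase", 3)
                for j in range(3)
            ]
            scenario = "CM"
        else:
            traits = [
                TraitMeta("trait1"), TraitMeta("trait2"),
                TraitMeta("trait3", "ordinal", 3, "increase", 3),
            ]
            scenario = "CCMM"

    n = n_train + n_cand
    pop = make_founders(n, n_loci, 0.5, n_generations=25, seed=rng)
    effects = traitsim.sample_effects(n_loci, corr, rng)
    gv = genetic_values(pop, effects)
    env_sd = traitsim.calibrate_environment(gv, 0.5)
    raw = phenotype(gv, env_sd, rng)

    obs = raw.copy()
    for j, t in enumerate(traits):
        if t.kind != "ordinal":
            continue
        if preset == "wheat-style":
            obs[:, j] = quartile_categorize(raw[:, j], t.n_categories, reverse=True)
        else:
            props = (
                traitsim.CM_CATEGORY_PROPORTIONS[j]
                if scenario == "CM"
                else traitsim.CCMM_CATEGORY_PROPORTIONS
            )
            thr = traitsim.thresholds_from_proportions(raw[:, j], props)
            obs[:, j] = discretize(raw[:, j], thr)

    kinds = tuple(t.kind for t in traits)
    names = [t.name for t in traits]
    train = slice(0, n_train)
    cand = slice(n_train, n)

    write_genotypes(pop.subset(pop.ids[train]), outdir / "genotypes.csv")
    write_genotypes(pop.subset(pop.ids[cand]), outdir / "candidates.csv")
    write_phenotypes(
        PhenotypeTable(pop.ids[train], obs[train], kinds), outdir / "phenotypes.csv",
        names,
    )
    truth = pd.DataFrame(gv, columns=[f"gv_{nm}" for nm in names])
    truth.insert(0, "id", pop.ids)
    truth.to_csv(outdir / "truth.csv", index=False, float_format=_FLOAT_FMT)
    config = RunConfig(
        scenario=scenario, traits=traits,
        mcmc=McmcSettings(iterations=500, burn_in=100, thin=4),
        selection_fraction=0.2, seed=seed, h2=0.5, preset=preset,
    )
    config.to_yaml(outdir / "config.yaml")
    return {
        "genotypes": outdir / "genotypes.csv",
        "candidates": outdir / "candidates.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.csv",
        "config": outdir / "config.yaml",
    }


# ---------------------------------------------------------------------------
# chain persistence (long-format CSV + YAML sidecar)


def _long_frame(arrays: dict) -> pd.DataFrame:
    rows = []
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        S = arr.shape[0]
        flat = arr.reshape(S, -1)
        for idx in range(flat.shape[1]):
            sub = np.unravel_index(idx, arr.shape[1:]) if arr.ndim > 1 else ()
            label = name + ("[" + ",".join(str(i + 1) for i in sub) + "]" if sub else "")
            rows.append(
                pd.DataFrame({"draw": np.arange(1, S + 1), "parameter": label,
                              "value": flat[:, idx]})
            )
    return pd.concat(rows, ignore_index=True)


def _unstack(df: pd.DataFrame, name: str, shape: tuple) -> np.ndarray:
    sub = df[df["parameter"].str.startswith(name + "[") | (df["parameter"] == name)]
    wide = sub.pivot(index="draw", columns="parameter", values="value")
    S = wide.shape[0]

    def key(label: str):
        if "[" not in label:
            return ()
        return tuple(int(x) for x in label[label.index("[") + 1 : -1].split(","))

    cols = sorted(wide.columns, key=key)
    return wide[cols].to_numpy().reshape((S,) + shape)


def save_chains(path, gaussian: GaussianChain | None, ordinals=()) -> None:
    """Persist chains under `path`: one CSV per model plus ``chains.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"ordinals": []}
    if gaussian is not None:
        _long_frame(
            {"mu0": gaussian.mu0, "beta": gaussian.beta, "sigma": gaussian.sigma,
             "effect_var": gaussian.effect_var}
        ).to_csv(path / "gaussian.csv", index=False, float_format=_FLOAT_FMT)
        meta["gaussian"] = {
            "n_markers": int(gaussian.n_markers),
            "n_traits": int(gaussian.n_traits),
            "x_center": [float(v) for v in gaussian.x_center],
        }
    for name, ch in ordinals:
        _long_frame(
            {"beta": ch.beta, "gamma": ch.thresholds, "effect_var": ch.effect_var}
        ).to_csv(path / f"ordinal_{name}.csv", index=False, float_format=_FLOAT_FMT)
        meta["ordinals"].append(
            {"name": name, "n_markers": int(ch.n_markers),
             "n_categories": int(ch.n_categories),
             "x_center": [float(v) for v in ch.x_center]}
        )
    (path / "chains.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_chains(path):
    """Inverse of :func:`save_chains`; returns (gaussian, [(name, chain), ...])."""
    path = Path(path)
    meta = yaml.safe_load((path / "chains.yaml").read_text())
    gaussian = None
    if "gaussian" in meta:
        m = meta["gaussian"]
        df = pd.read_csv(path / "gaussian.csv")
        p, t = m["n_markers"], m["n_traits"]
        gaussian = GaussianChain(
            mu0=_unstack(df, "mu0", (t,)),
            beta=_unstack(df, "beta", (p, t)),
            sigma=_unstack(df, "sigma", (t, t)),
            effect_var=_unstack(df, "effect_var", (t,)),
            x_center=np.asarray(m["x_center"], dtype=float),
        )
    ordinals = []
    for m in meta.get("ordinals", []):
        df = pd.read_csv(path / f"ordinal_{m['name']}.csv")
        p, K = m["n_markers"], m["n_categories"]
        ordinals.append(
            (
                m["name"],
                OrdinalChain(
                    beta=_unstack(df, "beta", (p,)),
                    thresholds=_unstack(df, "gamma", (K - 1,)),
                    effect_var=_unstack(df, "effect_var", ()),
                    x_center=np.asarray(m["x_center"], dtype=float),
                    n_categories=K,
                ),
            )
        )
    return gaussian, ordinals
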