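"""Population simulation: founders, gametes, and doubled-haploid offspring.

Genotypes are additive dosage codes for unlinked biallelic loci: a diploid
line carries 0, 1 or 2 copies of the counted allele per locus; a doubled
haploid (DH) line is fully homozygous and carries only 0 or 2. There is no
linkage map, mutation or dominance: loci segregate independently and the
only source of disequilibrium among founders is drift accumulated during
discrete generations of random mating in a finite population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIPLOID = "diploid"
DOUBLED_HAPLOID = "doubled-haploid"

__all__ = [
    "DIPLOID",
    "DOUBLED_HAPLOID",
    "Population",
    "make_founders",
    "gamete",
    "make_dh_offspring",
    "random_mating_generation",
]


@dataclass
class Population:
    """A cohort of lines with genotypes coded as additive dosages.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n_lines, n_loci)`` with values in
        ``{0, 1, 2}`` (diploid) or ``{0, 2}`` (doubled haploid).
    ids
        Unique line identifiers, one per row.
    generation
        Free-form generation label (e.g. ``"F0"``, ``"C3"``).
    ploidy_state
        Either :data:`DIPLOID` or :data:`DOUBLED_HAPLOID`.
    """

    genotypes: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    generation: str = "F0"
    ploidy_state: str = DIPLOID

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (lines x loci) array")
        n, p = self.genotypes.shape
        if n <= 0 or p <= 0:
            raise ValueError("population must have at least one line and one locus")
        if self.ids is None:
            self.ids = np.array([f"L{i + 1:04d}" for i in range(n)])
        else:
            self.ids = np.asarray(self.ids)
        if self.ids.shape[0] != n:
            raise ValueError("number of ids must match number of lines")
        if len(np.unique(self.ids)) != n:
            raise ValueError("line identifiers must be unique")
        vals = np.unique(self.genotypes)
        if self.ploidy_state == DOUBLED_HAPLOID:
            if not np.isin(vals, (0, 2)).all():
                raise ValueError(
                    "doubled-haploid genotypes must contain only dosages {0, 2}"
                )
        elif self.ploidy_state == DIPLOID:
            if not np.isin(vals, (0, 1, 2)).all():
                raise ValueError("diploid genotypes must contain only dosages {0, 1, 2}")
        else:
            raise ValueError(f"unknown ploidy_state: {self.ploidy_state!r}")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus frequency of the counted allele."""
        return self.genotypes.mean(axis=0) / 2.0

    def subset(self, ids) -> "Population":
        """Return the sub-population with the given identifiers (in order)."""
        ids = np.asarray(ids)
        lookup = {v: i for i, v in enumerate(self.ids)}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"unknown line identifiers: {missing[:5]}")
        rows = np.array([lookup[v] for v in ids])
        return Population(
            self.genotypes[rows], ids=ids.copy(), generation=self.generation,
            ploidy_state=self.ploidy_state,
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_bits(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    """An (n, p) array of i.i.d. fair bits, drawn bytewise for speed."""
    nbytes = (p + 7) // 8
    raw = rng.integers(0, 256, size=(n, nbytes), dtype=np.uint8)
    return np.unpackbits(raw, axis=1)[:, :p]


def _gametes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of `genotypes` (Mendelian segregation per locus).

    Dosage 0 -> allele 0, dosage 2 -> allele 1, dosage 1 -> fair coin;
    equivalently ``(dosage + bit) // 2`` with an independent fair bit.
    """
    g = genotypes.astype(np.uint8, copy=False)
    bits = _random_bits(rng, g.shape[0], g.shape[1])
    return (g + bits) >> 1


def gamete(parent_row: np.ndarray, seed=None) -> np.ndarray:
    """Sample one haploid gamete from a single diploid parent genotype.

    Per locus: dosage 0 transmits allele 0, dosage 2 transmits allele 1,
    and a heterozygote (dosage 1) transmits allele 1 with probability 1/2,
    independently across loci.
    """
    parent_row = np.asarray(parent_row)
    if parent_row.ndim != 1:
        raise ValueError("parent_row must be a 1-D genotype vector")
    if not np.isin(np.unique(parent_row), (0, 1, 2)).all():
        raise ValueError("parent genotype contains dosages outside {0, 1, 2}")
    rng = _as_rng(seed)
    return _gametes(parent_row[None, :], rng)[0]


def _distinct_parent_pairs(n: int, size: int, rng: np.random.Generator):
    """`size` ordered pairs of distinct parent indices drawn uniformly."""
    pa = rng.integers(0, n, size=size)
    pb = rng.integers(0, n, size=size)
    clash = pa == pb
    while clash.any():
        pb[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = pa == pb
    return pa, pb


def random_mating_generation(
    genotypes: np.ndarray, rng: np.random.Generator, n_offspring: int | None = None
) -> np.ndarray:
    """One discrete generation of random mating (monoecious, no selfing).

    Each offspring draws two distinct parents uniformly at random and
    receives one Mendelian gamete from each.
    """
    n = genotypes.shape[0]
    if n < 2:
        raise ValueError("random mating requires at least 2 parents")
    if n_offspring is None:
        n_offspring = n
    pa, pb = _distinct_parent_pairs(n, n_offspring, rng)
    return _gametes(genotypes[pa], rng) + _gametes(genotypes[pb], rng)


def make_founders(
    n_lines: int,
    n_loci: int,
    allele_freq: float = 0.5,
    n_generations: int = 200,
    seed=None,
) -> Population:
    """Simulate a founder population with drift-induced disequilibrium.

    Genotypes start as i.i.d. Binomial(2, `allele_freq`) dosages and then
    undergo `n_generations` of discrete-generation random mating at constant
    census size `n_lines`. With unlinked loci the expected heterozygosity
    decays by the Wright-Fisher factor (1 - 1/(2N)) per generation while the
    expected allele frequency stays at `allele_freq`.
    """
    if n_lines <= 0 or n_loci <= 0:
        raise ValueError("n_lines and n_loci must be positive")
    if not 0.0 < allele_freq < 1.0:
        raise ValueError("allele_freq must lie strictly between 0 and 1")
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    rng = _as_rng(seed)
    geno = rng.binomial(2, allele_freq, size=(n_lines, n_loci)).astype(np.uint8)
    for _ in range(n_generations):
        geno = random_mating_generation(geno, rng)
    return Population(geno, generation="F0", ploidy_state=DIPLOID)


def make_dh_offspring(
    parents: Population,
    selected_ids,
    n_offspring: int,
    seed=None,
    generation: str = "DH",
) -> Population:
    """Derive a doubled-haploid population from randomly paired parents.

    The selected parents are paired at random without replacement
    (``floor(k / 2)`` full-sib families); each pair produces a single F1
    genotype (one gamete from each parent), and every DH offspring of that
    family is one F1 gamete with its genome doubled. Offspring counts are
    split as evenly as possible across families.
    """
    selected_ids = np.asarray(selected_ids)
    if selected_ids.size < 2:
        raise ValueError("need at least 2 selected parents to form crosses")
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    rng = _as_rng(seed)
    sel = parents.subset(selected_ids)
    order = rng.permutation(sel.n_lines)
    n_pairs = sel.n_lines // 2
    base, extra = divmod(n_offspring, n_pairs)
    out = np.empty((n_offspring, parents.n_loci), dtype=np.uint8)
    row = 0
    for k in range(n_pairs):
        fam = base + (1 if k < extra else 0)
        if fam == 0:
            continue
        p1 = sel.genotypes[order[2 * k]]
        p2 = sel.genotypes[order[2 * k + 1]]
        f1 = _gametes(p1[None, :], rng)[0] + _gametes(p2[None, :], rng)[0]
        dh = 2 * _gametes(np.broadcast_to(f1, (fam, parents.n_loci)), rng)
        out[row : row + fam] = dh
        row += fam
    ids = np.array([f"{generation}_{i + 1:04d}" for i in range(n_offspring)])
    return Population(out, ids=ids, generation=generation, ploidy_state=DOUBLED_HAPLOID)
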