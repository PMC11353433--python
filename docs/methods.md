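# Methods

This note documents the models, the simulator, and the numerical and
design choices behind `pelselect`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Statistical models

**Multi-trait Gaussian marker regression.** Training lines with `t`
continuous traits follow `y_i ~ MVN(μ0 + B' x_i, Σ)` with marker
dosages `x_i` centered on the training means. Priors: marker effects
`β_jm ~ N(0, σ²_βj)` per trait (ridge), trait-specific effect variances
with scaled-inverse-χ² hyperpriors (`df = 5`, scale set so that the
prior mode attributes a proportion `r2 = 0.5` of each trait's
phenotypic variance to markers — the usual weakly informative variance
split), flat intercepts, and an unstructured inverse-Wishart residual
covariance with `t + 2` degrees of freedom and a diagonal scale at
`(1 − r2)·var(y)`. The Gibbs sampler updates `B` column-block-wise (one
trait at a time): the full conditional of `β_j` has precision
`(Σ⁻¹)_jj XᵀX + I/σ²_βj`, which is diagonal in the fixed eigenbasis of
`XᵀX`, so after a one-time eigendecomposition each draw costs `O(p²)`
and is algebraically exact. Inverse-Wishart draws use the Bartlett
construction directly on the package's `numpy` Generator so chains are
bit-reproducible for a fixed seed.

**Ordinal probit threshold regression.** Each ordinal trait is fitted
independently (of the other ordinals and of the continuous block):
liability `l_i = x_i'β + ε_i`, `ε_i ~ N(0, 1)` fixed for
identifiability, observed category `k` iff `γ_{k-1} < l_i ≤ γ_k`,
strictly ordered free thresholds and *no intercept* — the thresholds
act as intercepts (dosages are centered, so the thresholds absorb the
mean). Effects use the same ridge prior with the liability variance 1
in place of `var(y)`. Liabilities are drawn from truncated normals by
inverse-CDF; effects as above with unit residual variance.

*Threshold update.* The classic data-augmentation update (each `γ_k`
uniform between the adjacent categories' liability order statistics)
is a valid Gibbs step but mixes by `O(1/n)` random-walk increments,
because each threshold is pinned between adjacent liability order
statistics; at realistic training sizes its retained draws badly
understate the posterior spread of the thresholds. The package
therefore updates all thresholds with a joint random-walk
Metropolis step on the observed-data likelihood (liabilities
integrated out), with order-preserving truncated-normal proposals of
scale `0.5/√n` and the corresponding normalizer correction. Because
the liabilities are redrawn at the start of every iteration, mixing
Gibbs steps on `(l, β)` with a collapsed step on `γ | β, y` leaves the
joint posterior invariant. With this update the 90% intervals cover
the true thresholds at close to nominal rates in the recovery tests.

The printed probit expression is implemented in the standard
orientation `P(y = k) = Φ(γ_k − η) − Φ(γ_{k-1} − η)`, which is the
only orientation that is increasing in `k` for ordered thresholds.

**Joint predictive and loss.** For candidate `c` and retained draw
`s`, the continuous means `μ0^{(s)} + B^{(s)'} x_c` and latent ordinal
means `β^{(s)'} x_c` are stacked into one normal with covariance
`blockdiag(Σ^{(s)}, I)`; the identity latent block encodes the
assumed mutual independence and unit variance of the latent traits.
Draws across the independently fitted chains are paired by retained
index; since the chains are mutually independent, any pairing gives
the same expected loss. Per-draw losses evaluate the *distribution*
(the draw's full predictive normal), not a sampled phenotype:

- Kullback–Leibler loss (headline):
  `KL(target‖candidate) = ½[tr(Σc⁻¹Σt) + (μc−μt)'Σc⁻¹(μc−μt) − d + ln(det Σc/det Σt)]`.
- A direction-signed linear deviation loss as the simple alternative.

PEL is the plain average of per-draw losses; candidates are ranked
ascending with stable (input-order) tie-breaking, and the lowest
`ceil(fraction·n)` are selected.

**Target construction.** The reference literature leaves the target
distribution to the practitioner, so the package declares a default
and logs it with every run: continuous traits take the goal-direction
extreme of the candidates' posterior-mean breeding values (max for
increase, min for decrease); an ordinal trait preferring its top
category takes the posterior-mean top threshold plus a margin `δ`
(default 1.0, i.e. ~84% target mass on the preferred category under
the unit latent variance), mirrored for the bottom category, and the
mid-threshold interval midpoint for interior categories. The target
covariance is the identity (configurable scale). The construction is
reproducible and direction-faithful; other choices plug in through
`TargetSpec`.

## The simulator and what it emulates

**Founders.** Genotypes are additive dosages at unlinked biallelic
loci, initialized i.i.d. Binomial(2, 0.5) and put through 200
generations of discrete random mating at constant census size
(monoecious, two distinct parents per offspring, no selfing — the
standard convention; the full-scale preset uses 2000 lines × 8000
loci). Drift is the only source of disequilibrium: expected
heterozygosity decays by `(1 − 1/2N)` per generation (tested against
the closed form) while the expected allele frequency is a martingale.
Fair bits for Mendelian segregation are generated bytewise
(`unpackbits`), which keeps the full-scale founder simulation under
~10 s.

**Traits.** Every locus affects every trait (full pleiotropy) with
i.i.d. MVN effect vectors. The effect covariance uses unit variances
and correlations `(−0.37, 0.34, −0.02)` for pairs (1,2), (2,3), (1,3);
because the expected genetic-value covariance is proportional to the
effect covariance, the *realized* founder correlations — not the
matrix — are the contract, verified at full scale in the acceptance
checks. Environmental SDs are calibrated once on the founder
generation so `Var_A/(Var_A + σ²_e)` equals the configured `h²` (0.3
or 0.6) and are then held fixed; later cycles monitor, not re-impose,
heritability. Ordinal thresholds are placed at founder
liability-phenotype quantiles reproducing the scenario's category
proportions (CM: 49/34/17, 49/23/28, 14/36/50; CCMM trait 3:
49/19/32) and frozen so proportions can evolve across cycles.

**Cycle loop.** Each cycle: monitor the population (true-genetic-value
means, realized `h²`, category proportions of the liability
phenotypes under the frozen thresholds); split 70/30 into training and
candidates (re-randomized every cycle to avoid frozen-panel
artifacts); phenotype the training split; fit the Gaussian and ordinal
models; assemble the joint predictive for the candidates; rank by PEL
against the default target (preference for the top category of every
ordinal trait, increase for continuous ones); select 30% of the
candidate pool; random-pair the selected parents without replacement
(`⌊k/2⌋` full-sib families, offspring split evenly) and derive the
next cycle's doubled-haploid population at constant size. If
selection drives an ordinal category extinct in a training split, the
categories are re-coded to the observed contiguous set for that fit
(the fitting contract rejects unobserved categories); a trait with a
single observed category contributes a flat chain for that cycle.
Monte-Carlo replicates draw independent streams from the master seed
via `SeedSequence.spawn`, making whole programs bit-reproducible.

**What the simulator does not emulate.** No linkage map,
recombination hotspots, mutation, dominance/epistasis,
genotype-by-environment interaction, pedigree-based relatedness in the
fitted models, or correlated latent traits. Passing tests therefore
demonstrate internal consistency of the method under an idealized
additive architecture, not performance on real marker panels with LD
structure or non-additive variation.

## Analyses

`trend_slopes` fits least squares of each monitored quantity against
cycle per replicate; percent change per cycle is the slope divided by
that replicate's cycle-1 level ×100 and total change is
`(last − first)/first ×100` (a zero baseline leaves percents NaN —
continuous genetic-value means are near zero by construction, so
directional tests use raw slopes). Pooled rows average the
per-replicate statistics (the mean-of-changes convention).
`nonparametric_tests` runs Kruskal–Wallis across cycles plus all
pairwise two-sided Mann–Whitney U tests with Bonferroni correction
over the `C(C,2)` comparisons at `α = 0.05`, reported as an S/NS
lower-triangle matrix.

## Scales and defaults

- MCMC defaults: 6000 iterations, 1000 burn-in, thinning 5 (1000
  retained); `r2 = 0.5`; all configurable via `McmcSettings`.
- `full-scale` preset: 2000 lines, 8000 loci, 200 founder generations,
  10 cycles, 20 replicates — the headline experiment scale.
- `desk-test` preset: 300 lines, 500 loci, 100 founder generations, 5
  cycles, 5 replicates, short chains (600/200/4). This is the scale
  the test suite uses for the directional program checks; it
  reproduces signs and orderings of the gains, while matching printed
  magnitudes requires the full preset.
- Degenerate inputs: zero-variance traits, non-PSD covariances,
  unobserved categories, NaN losses and mismatched dimensions raise
  `ValueError` with the offending trait/candidate named; truncated
  normal draws are clipped at ±10 liability units when an interval's
  CDF mass underflows.

## Known limitations

- The independence of latent traits (identity latent block) discards
  cross-trait information in the ordinal block; the joint predictive
  is therefore deliberately suboptimal but matches current breeding
  practice for high-dimensional marker data.
- The default target construction depends on the candidate pool (its
  extremes move between cohorts); for cross-cohort comparability a
  fixed target should be supplied explicitly.
- Threshold Metropolis scale `0.5/√n` is not adapted; acceptance rates
  degrade for very small `n` (< ~50), where longer chains are advised.
- Percent-change summaries are meaningless when the cycle-1 baseline
  is near zero; use raw slopes there.
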