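# Methods

This note documents the models implemented in `ecoassembly`, the numerical
and design choices where more than one defensible option existed, and what
the synthetic-data generator does and does not emulate.

## Turnover null models

### βMNTD / βNTI

βMNTD is the abundance-weighted mean distance from each taxon in one
community to its nearest phylogenetic neighbour in the other community,
symmetrised over the pair. Taxa shared by both communities sit at distance
0 and therefore contribute nothing; the index is driven by the
phylogenetic placement of the taxa that differ. Units are those of the
tree's branch lengths (time, for a dated phylogeny).

The null model is a *taxa shuffle*: the taxon labels of the cophenetic
distance matrix are permuted uniformly at random, jointly for both
communities, leaving every abundance vector untouched. βNTI is the
z-score of the observed βMNTD within the null distribution, using the
sample standard deviation (ddof = 1), matching common ecology-package
convention. One permutation stream serves an entire turnover matrix: the
r-th permutation is applied to the distance matrix and βMNTD is recomputed
for all pairs, so results are reproducible from the seed alone and cannot
depend on execution order.

Degenerate nulls are flagged, not fudged. A pair of identical communities
(or a community containing every pool taxon, for NTI) has a permutation-
invariant statistic; its null standard deviation is zero and the pair is
excluded from classification rather than assigned a sentinel score. The
degeneracy test uses a relative floor (σ_null > 1e-10·max(|μ_null|, 1)) so
that floating-point summation noise is not mistaken for a usable null.

The shuffle pool at each habitat scale is the set of taxa *occurring in
that scale's samples*, not the full regional tree. Shuffling taxa that are
absent from a unit would leak regional phylogenetic structure into a local
null and defeat the purpose of scale restriction.

Abundance weighting is on by default (presence/absence weighting is a flag)
— the analysis consumes relative-abundance matrices throughout.

### Raup–Crick on Bray–Curtis (RC_Bray)

Null communities are assembled in the two-stage probabilistic recipe:
species identities drawn without replacement with probability proportional
to occupancy across the (scale-restricted) pool, then the remaining
individuals assigned multinomially with probability proportional to
pool-wide relative abundance. Every null community preserves its real
counterpart's observed richness and total read count; totals are the
observed ones, not rarefied. Observed Bray–Curtis is computed on counts to
match the nulls' count scale (a relative-abundance mode exists behind a
flag). Ties between null and observed BC count with weight ½ (mid-P), and
the quantile is rescaled to [−1, 1].

Per null replicate, one null community is drawn per pool sample and all
within-pool pairs are scored from that replicate's draws. The marginal
null distribution per pair is identical to drawing nulls pair-by-pair, at
1/(number of pairs) of the cost; the only difference is a weak correlation
between pairs' Monte-Carlo errors, which affects no reported statistic.
The full recipe (weighting flags, totals policy, seed) is recorded as
provenance on every result.

## Process classification and scale dependency

The (βNTI, RC) plane is partitioned exactly as the thresholds state, with
**strict** inequalities: |βNTI| > 2 ⇒ selection (sign gives heterogeneous
vs homogeneous); otherwise RC > 0.95 ⇒ dispersal limitation, RC < −0.95 ⇒
homogenizing dispersal, else drift. Boundary values (βNTI = ±2,
RC = ±0.95) fall through to the next rule; non-finite inputs are
"unclassified" and excluded from denominators.

Scales are the nested design levels region ⊃ site ⊃ plot ⊃ host. At each
level the null pool is one habitat unit's samples, and only within-unit
pairs are evaluated — the null pool is defined per unit, so cross-unit
pairs have no coherent null at that level. Units with fewer than 2 samples
are skipped with a logged warning. Per-unit seeds are derived
deterministically from the master seed and the unit key, so results do not
depend on iteration order.

The χ² test of scale dependency is a 2×S homogeneity test per process
(pairs assigned to the process vs not, across the S levels), with no
continuity correction; a 5×S omnibus variant is available behind a flag.
When the per-level proportions are exactly equal the statistic is returned
as exactly 0 (the floating-point computation is bypassed), and expected
cells below 1 are recorded as warnings. NTI per scale uses the same
pool-restriction logic, with a two-sided one-sample t test against 0 per
level and Tukey HSD across levels.

## Driver analysis

* **PCNM**: Euclidean distances truncated at the longest minimum-spanning-
  tree edge; distances beyond the threshold replaced by 4× the threshold;
  PCoA of the truncated matrix; positive-eigenvalue axes retained, ordered
  broad → fine.
* **PCA** of z-scored predictors (soil covariates, PCNM axes, and the
  first two PCoA axes of the host-plant phylogenetic distance matrix).
  Missing covariates are refused, never imputed. Axis signs follow a
  deterministic convention (largest-magnitude loading positive).
* **PCoA**: Gower double-centering and eigendecomposition; negative
  eigenvalues (Bray–Curtis and βNTI are semimetric) are reported, not
  corrected.
* **dbRDA**: the response distance matrix is PCoA-embedded and the
  retained axes regressed on predictors; on Euclidean distances this
  reproduces classical RDA exactly (tested to 1e-8). βNTI is not a
  distance — it is shifted by its minimum off-diagonal value to
  nonnegative before embedding, and the shift is recorded. Pairs whose
  null was degenerate are imputed with the mean valid score for the
  ordination only (they carry no information about the axes).
* **Forward selection**: at each step the candidate with the smallest
  permutation p of its partial pseudo-F enters (Freedman–Lane residual
  permutation under the reduced model; p = (1+#{F* ≥ F})/(1+n_perm)).
  Selection stops when no candidate reaches α or when cumulative adjusted
  R² (Ezekiel) would exceed the full model's adjusted R² — the standard
  double stopping rule guarding against inflation. An exact-fit tie
  tolerance of 1e-10 on the adjusted-R² comparison prevents the ceiling
  rule from rejecting a noiseless planted signal. An AIC-like value
  n·ln(RSS/n) + 2(q+1) is reported alongside but never used to stop.
  Under pure noise the realised per-candidate type-I rate is slightly
  below α (the ceiling rule is conservative); the calibration check
  accepts [0.005, 0.125] around α = 0.05.
* **Correlation screen**: Spearman ρ between ordination axes and external
  variables, Bonferroni-adjusted with family = number of tests performed
  in the run unless overridden.

## Synthetic-data generator

The generator emulates the data-generating structure the inference
assumes, with the study-shaped default design: 2 sites × 4 plots × 3 host
species × 4 individuals − 4 dropouts = 92 samples and a 449-leaf dated
birth–death phylogeny (birth 1.0, death 0.5 per unit time). Tests and the
acceptance script use a reduced 24-sample (2×2×2×3), 60-OTU configuration;
all qualitative behaviours reported are computed at that size.

* **Coordinates** are hierarchical — site centres 100 km apart, plot
  offsets within ±1 km, individuals within ±20 m — so PCNM axes separate
  scales by construction.
* **Niches** evolve by Brownian motion along the tree (rate 1.0 per unit
  branch time), giving the phylogenetic conservatism that makes βNTI an
  environmental-filtering proxy.
* **Latent environment** per sample = site contrast (± `env_contrast` ×
  niche SD, default 2.0) + plot jitter (0.2 SD) + host offset (0.1 SD) +
  noise (0.05 SD). Soil covariates pH/OM/GM are noisy linear maps of the
  standardized environment (e.g. pH = 7.0 + 0.6·z + N(0, 0.1)), giving the
  driver analysis a planted, recoverable signal.
* **Scenarios** multiply a lognormal regional base abundance by:
  - *env_filtering*: exp(−(env − niche)²/2σ²) with σ = `sigma_env` ×
    niche SD. The default σ = 0.4 with site contrast 2.0 SD defines the
    "strong filtering, contrasting environments" regime: it reliably
    separates the two sites' communities along conserved niches.
  - *dispersal_limitation*: exp(−distance/λ) from each taxon's home
    location (a uniformly chosen sampling point); λ defaults to 2 km, so
    the kernel is ≈ 0 between sites and ≈ 1 within a plot.
  - *homogenizing_dispersal*: per-plot lognormal perturbations mixed
    toward the regional pool with weight m (fully-mixed regime m = 0.99).
  - *neutral_drift*: an independent demographic chain per sample — the
    regional pool resampled through 2 multinomial generations of 2000
    individuals. This drift amplitude is comparable to the read-sampling
    noise at 2000 reads; much stronger drift concentrates communities
    onto few taxa whose one-off placement on the tree then dominates all
    pairwise scores, which is a mass-effect artefact rather than drift.
  Reads are multinomial at the configured depth; never-observed taxa are
  dropped and the tree pruned accordingly.
* **Ground truth** (environments, niche optima, taxon homes, scenario)
  is recorded before sampling noise and written as JSON.

What the generator does **not** emulate: sequencing error, PCR/chimera
artefacts, compositional biases of library preparation, temporal dynamics,
speciation, or interactions between taxa. Passing the planted-recovery
tests therefore shows the inference recovers the assembly regime from
ideal count data of realistic shape — not that it is robust to every
artefact of real amplicon surveys.

## Problem sizes and numerical notes

Null-model defaults are 999 replicates (matching field convention); the
test-suite and acceptance runs use 299–999 depending on the check, at the
24 × 60 reduced size. βMNTD for all pairs is computed by one vectorised
nearest-taxon reduction per sample per permutation, so a 999-replicate
region-level matrix takes well under a second at the reduced size.
Cophenetic distances are cached per dataset. All randomness flows through
named integer seeds (`numpy.random.default_rng`; dendropy's tree simulator
gets a `random.Random` seeded the same way), and identical inputs + seed
reproduce byte-identical outputs, including CSV files.

Known limitations: the Raup–Crick recipe is one member of a family (fixed
vs rarefied totals, occupancy vs uniform draws) and results can shift
between members — the recipe used is pinned in output provenance; βNTI
inherits the usual sensitivity to tree calibration; and the dbRDA response
embedding of βNTI (shift-to-nonnegative) is one defensible convention
among several, recorded in provenance.
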