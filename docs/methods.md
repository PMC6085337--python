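# Methods

`mutualinet` implements a trait-based analysis of mutualistic bipartite
networks: (i) an ordination-based test of whether trait matching between
plants and animals structures who interacts with whom, and (ii) a
hierarchical structural model of how climate-driven shifts in plant and
animal functional diversity propagate, bottom-up and top-down, into the
interaction niches of the other trophic level. This note documents the
models, the defaults and the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model

Three tables describe one mutualism (bird–fruit, bird–flower or
insect–flower):

* a plant trait table **R** (m × p) and an animal trait table **Q**
  (n × a), each with exactly one quantitative trait per functional role —
  *matching* (size-matching morphology, e.g. fruit diameter / bill
  width), *energy* (resource provisioning / energy requirement, e.g.
  crop mass / body mass) and *foraging* (stratum and mobility, e.g.
  plant height / Kipp's index);
* a binary metaweb **L** (m × n), 1 where a pair was observed
  interacting at least once across all sites, with zero-degree species
  pruned;
* per-site weighted networks (summed interaction counts) and site
  covariates: mean annual temperature (MAT, °C), mean annual
  precipitation (MAP, mm yr⁻¹), binary land use (LU) and elevation.

All traits are square-root transformed before analysis; ratio traits
(Kipp's index, forewing index) are formed before the transform. Missing
values are NaN, never zero. Missing climate values are imputed by OLS on
a third-order elevation polynomial plus additive habitat indicators;
missing traits by log–log allometry (e.g. bee body length from
intertegular distance) or by taxonomic relatives (genus → family → order
means, with the provenance level recorded).

## Trait matching: degree-weighted RLQ and fourth-corner tests

The metaweb is treated as a correspondence-analysis table: P = L / ΣL,
row weights r (plant relative degree) and column weights c (animal
relative degree). Traits are centred and scaled to unit variance under
these weights, and the p × a cross-covariance matrix

Ω = R̃ᵀ (P − r cᵀ) Q̃

is decomposed by SVD. The unit-norm coefficient vectors u_k, v_k
maximise the squared cross-covariance of the species scores x_k = R̃u_k,
y_k = Q̃v_k, with (x_kᵀ P y_k)² = λ_k. Verbal descriptions of the
trait weighting in the RLQ literature ("diagonal matrices of variable
weights") are dimensionally ambiguous; we adopt the convention above — degree-weighted
trait standardisation with unit-norm coefficients — and verify the
stated maximisation property directly against brute-force maximisation
over random unit coefficient vectors (the test suite checks λ₁ to 1e−3
and Σλ = ‖Ω‖²_F to 1e−10 on random instances). Axis signs are fixed by
making the largest-magnitude loading per axis positive. Axes are kept up
to 99% cumulative cross-covariance, with a floor of two.

Significance is assessed by fourth-corner permutation: model 2 permutes
plant identities (rows), model 4 animal identities (columns), and
model 6 reports the maximum of the two p-values — the only combination
that controls the type-I error of the fourth-corner problem, and a
deliberately conservative one: measured type-I error of the model-6 Σλ
test on trait-independent synthetic data is ≈ 0.00–0.01 at α = 0.05.
P-values use the add-one estimator, ties counted as extreme. The default
is 9,999 permutations; the test suite and example analyses use 999 (199
for power curves). Statistics available: Σλ (global association,
upper-tailed), per-axis score correlations, and per-trait
trait-vs-other-side-axis correlations (both two-sided). Evidence is
aggregated over trait types and mutualisms with Moran's exact Bernoulli
probability P = C(N, K) α^K (1−α)^(N−K) for K significant tests out of
N, computed in log space.

## Functional diversity and interaction niches

Functional dispersion (FDis) is the abundance-weighted mean distance of
species to the abundance-weighted centroid in a PCoA embedding of
range-standardised Gower distances; abundances are the species' marginal
interaction totals in the site network. By default the trait space is
built **once per mutualism × trophic level** over the pooled interacting
species (ranges over the pool), and every community is measured in that
common space — the convention of the standard FDis implementations. The
alternative, re-standardising ranges within each community, makes FDis
invariant to uniform scaling of a community's trait spread and therefore
blind to climate-driven expansion or contraction of the realised trait
space, which is the signal of interest here; that mode is kept as an
option (`ranges="community"`) and both are tested. Negative PCoA
eigenvalues are dropped (no Cailliez/Lingoes correction): quantitative
range-standardised Gower distances on three traits are near-Euclidean,
and dropped-axis distortion is checked by the oracle tests. Communities
with fewer than two interacting species get FDis = 0 and a flag.
Univariate FDis (matching-, energy- or foraging-trait space alone) is
computed the same way.

Niche breadth of a species is e^H, the exponential of the Shannon
entropy of its link proportions (effective number of partners,
1 ≤ e^H ≤ degree). Niche partitioning is the standardised
Kullback–Leibler specialisation d′: the divergence d of a species'
partner use from partner availability (column marginals), rescaled by
the minimum and maximum divergence achievable at its integer interaction
total. The maximum is a greedy reallocation concentrating interactions
on the least-available partners subject to partner-marginal caps, the
minimum a largest-remainder rounding of the proportional allocation —
both mirror the established d′ reference implementation and are
heuristics; exhaustive enumeration over all 2×2 and 2×3 integer webs
with totals ≤ 6 confirms the observed d always lies inside the
enumerated bounds and that reciprocal perfect specialists score d′ = 1.
Network-level summaries are unweighted arithmetic means over species
(the source description says only "mean"); an abundance-weighted mean is
available. e^H is ln-transformed and all model variables are z-scaled
globally across the pooled table (the structural model pools mutualisms
with a random factor) before model fitting.

## Hierarchical structural equation model

Two models share one path topology, one with (ln e^H_p, ln e^H_a) and
one with (d′_p, d′_a) as the niche pair:

* FD_p, FD_a ~ MAT + MAP + LU
* niche_p, niche_a ~ MAT + MAP + LU + FD_p + FD_a

Each equation has crossed random intercepts for site and mutualism, and
the (FD_p, FD_a) and (niche_p, niche_a) pairs have correlated bivariate
residuals (covariances always included, never under selection — they
absorb reciprocal effects and shared unmeasured drivers). Priors:
Normal(0, 10²) on coefficients and intercepts, half-Cauchy(2.5) on all
standard deviations, Uniform(−1, 1) on residual correlations.

Path selection uses Gibbs variable selection with binary indicators:
β_k = γ_k·θ_k, γ_k ~ Bernoulli(½). When γ_k = 0 the slab is drawn from
a pseudo-prior set to the posterior mean/s.d. of a pilot run without
selection — the "global adaptation" step that lets chains cross between
inclusion states freely. Evidence per path is 2·ln(BF) from the
posterior inclusion frequency against the prior odds (thresholds 2/6/10
for positive/strong/decisive); inclusion frequencies of exactly 0 or 1
are clipped to the 1/(n_draws+1) margin and flagged as saturated.
Conditional-on-inclusion posterior means and 95% intervals are reported
per path. Model fit is summarised by marginal and conditional r² per
endogenous variable (fixed-effects variance share vs. fixed + random,
from the per-draw variance components).

The sampler is a blocked Gibbs scheme written in numpy: conjugate normal
updates for coefficients and random intercepts using the conditional
(given the paired equation's residual) Gaussian likelihood; conjugate
inverse-gamma updates for random-effect scales via the scale-mixture
representation of the half-Cauchy; univariate slice sampling for the
residual-block scales and correlation; and an exact translation Gibbs
step that re-centres each random-intercept block against the fixed
intercept (the likelihood-flat direction that otherwise mixes slowly).
The full field-study schedule (8 chains × 51,000 iterations, 1,000 burn-in,
thinning 100 → 4,000 retained draws) is the default; a desk schedule
(4 × 5,000, thinning 10 → 1,600 draws) is used by the test suite and the
example analyses. Convergence (split-R̂ < 1.05 target, < 1.1 flag) and
bulk ESS are computed with ArviZ; everything is reproducible from a
single seed via CRC-derived sub-seeds.

## Synthetic data

The generator emulates the study's structure with known ground truth.

`simulate_dataset` builds the full object stack: 53 sites along an
elevational gradient with MAT falling ~linearly (≈ 24 °C → 4 °C) and MAP
unimodal (peak near 2,200 m); per mutualism, pools of 40 plant and 40
animal species with latent traits ~ N(4, 1) on the square-root scale
(stored squared, so the pipeline's transform recovers them exactly);
site communities realised by log-normal abundances (σ = 0.8) shaded by a
Gaussian trait window whose width scales as exp(0.35·β·z(climate)) —
MAP for plants, MAT for animals (β = 0.5 by default); pair intensities
∝ abundance × exp(−Δt²/2σ²) on matching traits (σ = 0.5 default; a
threshold "forbidden link" kernel is available) × energy/foraging
alignment terms (slopes 0.3/0.2); counts Poisson with ~150 interactions
per site network (≈ the field study's per-network mean), negative
binomial optionally. `null_dataset` drops every trait term. Site counts
per mutualism default to 39/20/19 on the shared pool, as in the field
design.

`simulate_sem_table` draws the site-metrics table directly from the
structural equations (n = 42 sites × 3 mutualisms = 126 rows by
default): z-scaled exogenous variables, then FD and niche variables with
the configured path coefficients (defaults mirror the study's supported
paths at standardised effect 0.5, MAT→niche at 0.3, all others 0),
site/mutualism intercept s.d.s 0.3/0.2, residual s.d. 0.8 with residual
correlations 0.3. This is the exact data-generating process the SEM
assumes and is used for parameter-recovery and selection
operating-characteristic tests (effect size 0.6 for the
operating-characteristic scenario).

What the generator does **not** emulate: phenology and seasonal
turnover, spatial autocorrelation among sites, mechanistic foraging
behaviour, sampling effort heterogeneity, and taxonomic structure in the
trait distributions. Passing tests therefore show that the estimators
recover the quantities they target under the assumed generative
structure, not that the field data meet those assumptions.

## Problem sizes and tolerances

Oracle equivalences are asserted tightly (λ₁ vs brute force 1e−3 with a
20,000-direction search; Σλ identity 1e−10; FDis vs hand formula 1e−10;
d′ bounds by exhaustive enumeration). Monte-Carlo suites use: 200
trait-independent replicates (999 permutations) for the type-I bound
≤ 0.08; 50 replicates per size (30/50/100 species per side, 199
permutations) for power monotonicity; 12 replicates of the n = 126 SEM
scenario for operating characteristics (≥ 90% recovery within 3
posterior s.d., ≥ 90% support for effect-0.6 paths, ≥ 80% quiet null
paths), chosen to keep the full suite around three minutes on one CPU
while leaving the binomial error of each rate well inside its margin.
The acceptance script recomputes the same quantities at slightly smaller
replicate counts. Degenerate cases: constant traits are rejected in the
ordination (zero weighted variance) and yield FDis 0 in communities;
degenerate permutations are resampled and logged; d_max = d_min gives
d′ = 0; saturated inclusion frequencies are clipped and flagged.

## Known limitations

* The RLQ centering/scaling convention is validated against internal
  properties and oracles, not against the original (embargoed)
  data-dependent eigenvalues.
* The d′ extremes are heuristics outside the exhaustively enumerated
  regime; d′ is clipped to [0, 1].
* The pseudo-prior adaptation uses a single pilot run; pathological
  multimodality in the pilot would propagate to the selection step.
* Categorical or fuzzy traits, other FD indices (FRic, FEve, Rao Q),
  network-level H₂′, and spatial interpolation of climate are out of
  scope.
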