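# mutualinet

Trait-based analysis of mutualistic plant–animal networks: does trait
matching decide who interacts with whom, and do climate-driven shifts in
plant and animal functional diversity control the interaction niches of
the other trophic level (bottom-up vs. top-down assembly)?

The package is written for ecologists working with bipartite interaction
data (seed-dispersal and pollination networks) sampled across
environmental gradients, together with quantitative functional traits
for both trophic levels. Because such field data are often embargoed or
expensive, a first-class synthetic-data module generates datasets with
the same statistical structure and known ground truth; every estimator
in the package is validated against it.

## What it computes

* **Trait matching** — a degree-weighted RLQ co-inertia ordination of
  plant traits R, animal traits Q and the binary metaweb L. With
  P = L/ΣL and traits standardised under the CA row/column weights
  (relative species degree), the SVD of Ω = R̃ᵀ(P − rcᵀ)Q̃ yields trait
  syndromes u_k, v_k whose species scores have maximal squared
  cross-covariance (x_kᵀPy_k)² = λ_k. Significance via fourth-corner
  permutation tests (model 2 = plant identities, model 4 = animal
  identities, model 6 = max of both p-values), and Moran's exact
  Bernoulli probability P = C(N,K)·α^K(1−α)^(N−K) to aggregate K
  significant tests out of N across mutualisms.
* **Functional diversity** — abundance-weighted functional dispersion
  (FDis): mean distance to the abundance-weighted centroid in a PCoA of
  range-standardised Gower distances, with marginal interaction totals
  as abundances; multivariate and per trait type (matching / energy /
  foraging).
* **Interaction niches** — niche breadth as the mean effective number of
  partners e^H (exponential Shannon entropy of link proportions) and
  niche partitioning as the mean standardised Kullback–Leibler
  specialisation d′ ∈ [0, 1].
* **Hierarchical SEM** — a Bayesian structural equation model on
  z-scaled site metrics: {MAT, MAP, LU} → {FD_p, FD_a} → {niche_p,
  niche_a}, crossed site/mutualism random intercepts, correlated
  residual pairs, and Kuo–Mallick-style indicator variable selection
  with globally adapted pseudo-priors. Evidence per path is 2·ln(Bayes
  factor) (>2 positive, >6 strong, >10 decisive); fit is marginal vs.
  conditional r².

See `docs/methods.md` for the full model descriptions and defaults.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_dataset.py --seed 1        # results/data/
python analysis/02_trait_associations.py --seed 1      # RLQ + fourth corner
python analysis/03_functional_diversity_niches.py      # FDis, e^H, d'
python analysis/04_structural_equation_models.py --seed 1
```

Step 02 prints, per mutualism (synthetic data, seed 1):

```
bird-flower: metaweb 38x39, sum(lambda) = 0.398 (model-6 P = 0.0010); axes kept = 2 ([94.   5.1]% of cross-covariance); axis-1 score correlation r = 0.58 (P = 0.0010)
bird-fruit: metaweb 38x39, sum(lambda) = 0.324 (model-6 P = 0.0010); axes kept = 3 ([95.4  3.4  1.1]% of cross-covariance); axis-1 score correlation r = 0.48 (P = 0.0010)
insect-flower: metaweb 37x38, sum(lambda) = 0.375 (model-6 P = 0.0010); axes kept = 2 ([95.8  3.4]% of cross-covariance); axis-1 score correlation r = 0.57 (P = 0.0010)
trait type 'matching': 6/6 axis-1 tests significant, Moran P = 1.56e-08
```

Read: in each simulated mutualism the global plant–animal trait
association (Σλ) is far beyond its permutation null (P = 0.001 at 999
permutations), the first ordination axis carries ≥ 94% of the
cross-covariance, and all six matching-trait tests on axis 1 are
individually significant — a coincidence with probability 1.6 × 10⁻⁸
under Moran's equation, i.e. strong evidence that size matching
structures these networks (as the generator intended).

Step 03 summarises the site metrics (`corr(MAP, FD_p) = 0.56;
corr(MAT, FD_a) = 0.44`), and step 04 fits both structural models;
with the desk MCMC schedule it reports, for the niche-breadth model:

```
niche breadth (ln e^H): 3 supported paths (2 ln BF > 2)
     MAP -> FD_p     beta = +0.59, 2lnBF = 14.8 (decisive (saturated))
     MAT -> FD_a     beta = +0.45, 2lnBF = 5.6 (positive)
    FD_a -> niche_p  beta = +0.54, 2lnBF = 14.8 (decisive (saturated))
```

Read: precipitation limits plant functional diversity, temperature
limits animal functional diversity, and animal functional diversity
propagates top-down into the niche breadth of plants — the
bottom-up/top-down structure built into the generative scenario, with
standardised effect sizes recovered near their true values.

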