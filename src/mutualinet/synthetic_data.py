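"""Synthetic mutualistic-network datasets with known ground truth.

The real system this emulates: three mutualisms (bird–fruit,
bird–flower, insect–flower) sampled on sites spanning a large
elevational gradient, where mean annual temperature falls roughly
linearly with elevation and precipitation peaks at mid elevation.
Interactions are driven bottom-up/top-down by trait matching: a pair's
interaction intensity decays with the distance between its matching
traits, modulated by energy and foraging trait alignment.  Climate
shapes functional diversity: the dispersion of the plant traits
realised at a site grows with precipitation, that of animal traits
with temperature.

Two generators are provided:

* :func:`simulate_dataset` builds the full object stack (trait tables,
  interaction records, covariates) by simulating communities and
  Poisson interaction counts, for testing the ordination/diversity
  pipeline end to end;
* :func:`simulate_sem_table` draws a site-metrics table directly from
  the structural equations (linear paths, crossed site/mutualism
  random intercepts, correlated bivariate residuals) — the exact
  data-generating process the hierarchical SEM assumes, for parameter-
  recovery and selection operating-characteristic tests.

:func:`null_dataset` removes all trait dependence from the interaction
intensities (abundance structure only) for type-I-error suites.

Trait values are generated on a latent (square-root) scale and stored
squared, so that the square-root transform used throughout the
analysis recovers the latent values exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import spawn_seed, zscale
from .core_data import (
    InteractionData,
    SiteCovariates,
    TraitTable,
    write_dataset,
)

DEFAULT_MUTUALISMS = {"bird-fruit": 39, "bird-flower": 20, "insect-flower": 19}

#: default structural coefficients (standardised scale); unlisted paths are 0
DEFAULT_SEM_COEFFICIENTS = {
    ("MAP", "FD_p"): 0.5,
    ("MAT", "FD_a"): 0.5,
    ("FD_p", "niche_a"): 0.5,
    ("FD_a", "niche_p"): 0.5,
    ("MAT", "niche_p"): 0.3,
    ("MAT", "niche_a"): 0.3,
}

_ENDOGENOUS = ("FD_p", "FD_a", "niche_p", "niche_a")
_PARENTS = {
    "FD_p": ("MAT", "MAP", "LU"),
    "FD_a": ("MAT", "MAP", "LU"),
    "niche_p": ("MAT", "MAP", "LU", "FD_p", "FD_a"),
    "niche_a": ("MAT", "MAP", "LU", "FD_p", "FD_a"),
}


@dataclass
class ScenarioConfig:
    """Generative scenario; defaults emulate the field study's conditions.

    ``sigma_match`` is the width (latent trait units; latent traits have
    s.d. ≈ 1) of the Gaussian matching kernel
    exp(−(t_p − t_a)²/(2σ²)); ``np.inf`` switches matching off.  The
    ``threshold`` kernel instead forbids links where the plant trait
    exceeds the animal trait by more than ``sigma_match`` (small-billed
    birds cannot take large fruits).
    """

    mutualisms: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MUTUALISMS))
    n_sites_total: int = 53
    n_plants: int = 40
    n_animals: int = 40
    sigma_match: float = 0.5
    kernel: str = "gaussian"  # or "threshold"
    energy_slope: float = 0.3
    foraging_slope: float = 0.2
    fd_map_effect: float = 0.5  # plant trait-pool dispersion ~ MAP
    fd_mat_effect: float = 0.5  # animal trait-pool dispersion ~ MAT
    site_totals: float = 150.0  # expected interaction count per site network
    abundance_sd: float = 0.8  # log-normal species abundance s.d.
    overdispersion: float | None = None  # negative-binomial shape; None = Poisson
    sem_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_SEM_COEFFICIENTS))
    site_sd: float = 0.3
    mutualism_sd: float = 0.2
    resid_sd: float = 0.8
    resid_cor_fd: float = 0.3
    resid_cor_niche: float = 0.3
    n_sites_sem: int = 42  # sites per mutualism in the direct SEM draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_match <= 0:
            raise ValueError("sigma_match must be > 0 (use np.inf to disable matching)")
        for name, val in (("site_sd", self.site_sd), ("mutualism_sd", self.mutualism_sd), ("resid_sd", self.resid_sd)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, val in (("resid_cor_fd", self.resid_cor_fd), ("resid_cor_niche", self.resid_cor_niche)):
            if not -1 < val < 1:
                raise ValueError(f"{name} must be in (-1, 1)")
        if self.kernel not in ("gaussian", "threshold"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every dataset; sufficient to re-simulate."""

    config: dict
    seed: int
    site_dispersion_plant: dict = field(default_factory=dict)
    site_dispersion_animal: dict = field(default_factory=dict)
    coefficients: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["coefficients"] = {f"{s}->{t}": v for (s, t), v in self.coefficients.items()}
        cfg = dict(payload["config"])
        if isinstance(cfg.get("sem_coefficients"), dict):
            cfg["sem_coefficients"] = {
                f"{s}->{t}": v for (s, t), v in cfg["sem_coefficients"].items()
            }
        payload["config"] = cfg
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


# ---------------------------------------------------------------------------
# site environment


def _make_sites(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates along a synthetic elevational gradient.

    MAT decreases ~linearly with elevation; MAP is unimodal, peaking
    near 2200 m.  Habitat bands follow elevation; land use is assigned
    within bands so LU is crossed with elevation.
    """
    n = cfg.n_sites_total
    elev = np.sort(rng.uniform(870, 4400, size=n))
    mat = 24.0 - 5.6 * (elev - 870) / 1000.0 + rng.normal(0, 0.4, n)
    map_ = 600.0 + 1900.0 * np.exp(-(((elev - 2200.0) / 800.0) ** 2)) + rng.normal(0, 80, n)
    bands = ["savanna", "lower-montane", "mid-forest", "upper-forest", "subalpine", "alpine"]
    band_idx = np.clip(((elev - 870) / (4400 - 870) * len(bands)).astype(int), 0, len(bands) - 1)
    lu = rng.integers(0, 2, size=n)
    habitat = [f"{bands[b]}{'-anthropogenic' if l else ''}" for b, l in zip(band_idx, lu)]
    ids = [f"S{i:02d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {"MAT": mat, "MAP": map_, "LU": lu, "elevation": elev, "habitat": habitat},
        index=pd.Index(ids, name="site_id"),
    )


def _latent_traits(rng: np.random.Generator, n: int, prefix: str) -> pd.DataFrame:
    """Latent (sqrt-scale) traits: matching/energy/foraging ~ N(4, 1), > 0."""
    lat = rng.normal(4.0, 1.0, size=(n, 3))
    lat = np.clip(lat, 0.1, None)
    ids = [f"{prefix}{i:03d}" for i in range(1, n + 1)]
    return pd.DataFrame(lat, index=pd.Index(ids, name="species_id"), columns=["matching", "energy", "foraging"])


def _kernel(cfg: ScenarioConfig, tp: np.ndarray, ta: np.ndarray) -> np.ndarray:
    diff = tp[:, None] - ta[None, :]
    if cfg.kernel == "threshold":
        # forbidden links: plant structure larger than animal apparatus + tolerance
        return np.where(diff <= cfg.sigma_match, 1.0, 1e-6)
    if np.isinf(cfg.sigma_match):
        return np.ones_like(diff)
    return np.exp(-(diff**2) / (2.0 * cfg.sigma_match**2))


def simulate_dataset(
    config: ScenarioConfig | None = None, trait_independent: bool = False
) -> tuple[TraitTable, TraitTable, InteractionData, SiteCovariates, SyntheticTruth]:
    """Simulate trait tables, interaction records and covariates.

    Per mutualism, species pools get fixed latent traits; per site, the
    community realises species abundances whose matching-trait spread
    widens with MAP (plants) or MAT (animals); pair intensities combine
    abundances with the matching kernel and energy/foraging modulation,
    and counts are Poisson (optionally negative-binomial).  With
    ``trait_independent=True`` all trait terms are dropped
    (intensity from abundances only).
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(spawn_seed(cfg.seed, "dataset"))
    sites = _make_sites(cfg, rng)
    z_map = zscale(sites["MAP"].to_numpy())
    z_mat = zscale(sites["MAT"].to_numpy())

    plant_tables, animal_tables, all_records = [], [], []
    disp_p: dict[str, float] = {}
    disp_a: dict[str, float] = {}
    site_ids = list(sites.index)

    for mutualism, n_sites in sorted(cfg.mutualisms.items()):
        tag = "".join(w[:2] for w in mutualism.split("-"))
        plants = _latent_traits(rng, cfg.n_plants, f"P_{tag}_")
        animals = _latent_traits(rng, cfg.n_animals, f"A_{tag}_")
        plant_tables.append(plants)
        animal_tables.append(animals)
        chosen = sorted(rng.choice(len(site_ids), size=min(n_sites, len(site_ids)), replace=False))
        tp = plants["matching"].to_numpy()
        ta = animals["matching"].to_numpy()
        ep = zscale(plants["energy"].to_numpy())
        ea = zscale(animals["energy"].to_numpy())
        fp = zscale(plants["foraging"].to_numpy())
        fa = zscale(animals["foraging"].to_numpy())
        if trait_independent:
            K = np.ones((cfg.n_plants, cfg.n_animals))
        else:
            K = _kernel(cfg, tp, ta)
            K = K * np.exp(cfg.energy_slope * np.outer(ep, ea) + cfg.foraging_slope * np.outer(fp, fa))

        for s in chosen:
            sid = site_ids[s]
            # community trait windows: wider with MAP (plants) / MAT (animals)
            tau_p = np.exp(0.35 * cfg.fd_map_effect * z_map[s])
            tau_a = np.exp(0.35 * cfg.fd_mat_effect * z_mat[s])
            disp_p[f"{mutualism}:{sid}"] = float(tau_p)
            disp_a[f"{mutualism}:{sid}"] = float(tau_a)
            ab_p = np.exp(rng.normal(0, cfg.abundance_sd, cfg.n_plants))
            ab_a = np.exp(rng.normal(0, cfg.abundance_sd, cfg.n_animals))
            if not trait_independent:
                # climate widens/narrows the realised trait window of the
                # community around the pool centre, across all three traits
                dev_p = ((plants.to_numpy() - 4.0) ** 2).sum(axis=1)
                dev_a = ((animals.to_numpy() - 4.0) ** 2).sum(axis=1)
                ab_p = ab_p * np.exp(-dev_p / (2 * tau_p**2))
                ab_a = ab_a * np.exp(-dev_a / (2 * tau_a**2))
            lam = np.outer(ab_p, ab_a) * K
            total = lam.sum()
            if total <= 0:
                raise ValueError("interaction intensity collapsed to zero; check config")
            lam = lam / total * cfg.site_totals
            if cfg.overdispersion:
                shape = cfg.overdispersion
                lam = rng.gamma(shape, lam / shape)
            counts = rng.poisson(lam)
            pi, ai = np.nonzero(counts)
            if pi.size == 0:
                continue
            all_records.append(
                pd.DataFrame(
                    {
                        "site_id": sid,
                        "mutualism": mutualism,
                        "plant_id": plants.index.to_numpy()[pi],
                        "animal_id": animals.index.to_numpy()[ai],
                        "count": counts[pi, ai],
                    }
                )
            )

    records = pd.concat(all_records, ignore_index=True)
    trait_types = {"matching": "matching", "energy": "energy", "foraging": "foraging"}
    plants_all = pd.concat(plant_tables) ** 2  # stored on raw scale; sqrt recovers latent
    animals_all = pd.concat(animal_tables) ** 2
    truth = SyntheticTruth(
        config=asdict(cfg) | {"trait_independent": trait_independent},
        seed=cfg.seed,
        site_dispersion_plant=disp_p,
        site_dispersion_animal=disp_a,
        coefficients=dict(cfg.sem_coefficients),
    )
    return (
        TraitTable(plants_all, trait_types, "plant", {"matching": "mm", "energy": "g", "foraging": "m"}),
        TraitTable(animals_all, trait_types, "animal", {"matching": "mm", "energy": "g", "foraging": "ratio"}),
        InteractionData(records),
        SiteCovariates(sites),
        truth,
    )


def null_dataset(
    config: ScenarioConfig | None = None,
) -> tuple[TraitTable, TraitTable, InteractionData, SiteCovariates, SyntheticTruth]:
    """Dataset with interactions independent of all traits (null model)."""
    return simulate_dataset(config, trait_independent=True)


# ---------------------------------------------------------------------------
# direct draw from the structural equations


def simulate_sem_table(config: ScenarioConfig | None = None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a site-metrics table directly from the structural equations.

    Exogenous MAT/MAP are z-scaled site-level normals, LU a z-scaled
    site-level Bernoulli(1/2); endogenous FD then niche variables follow
    the linear structural equations with crossed site and mutualism
    random intercepts and correlated bivariate residuals within the
    (FD_p, FD_a) and (niche_p, niche_a) pairs.

    Returns a frame with one row per site × mutualism (``n_sites_sem`` ×
    3 rows) and the ground truth.
    """
    cfg = config or ScenarioConfig()
    n_site = cfg.n_sites_sem
    muts = sorted(cfg.mutualisms)
    n_mut = len(muts)
    if n_site * n_mut < 30:
        raise ValueError("need n_sites_sem x n_mutualisms >= 30")
    rng = np.random.default_rng(spawn_seed(cfg.seed, "sem-table"))

    mat = rng.standard_normal(n_site)
    map_ = rng.standard_normal(n_site)
    lu_raw = rng.integers(0, 2, size=n_site).astype(float)
    if lu_raw.std() == 0:  # pragma: no cover - tiny-n corner
        lu_raw[0] = 1 - lu_raw[0]
    lu = (lu_raw - lu_raw.mean()) / lu_raw.std(ddof=1)

    site_idx = np.repeat(np.arange(n_site), n_mut)
    mut_idx = np.tile(np.arange(n_mut), n_site)
    n = n_site * n_mut
    X = {"MAT": mat[site_idx], "MAP": map_[site_idx], "LU": lu[site_idx]}

    coef = {k: float(v) for k, v in cfg.sem_coefficients.items()}

    def beta(src, tgt):
        return coef.get((src, tgt), 0.0)

    def bivariate_resid(rho):
        cov = cfg.resid_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        if cfg.resid_sd > 0:
            np.linalg.cholesky(cov + 1e-15 * np.eye(2))
        return rng.multivariate_normal([0.0, 0.0], cov, size=n)

    values = dict(X)
    for pair, rho in (( ("FD_p", "FD_a"), cfg.resid_cor_fd), (("niche_p", "niche_a"), cfg.resid_cor_niche)):
        eps = bivariate_resid(rho)
        for j, tgt in enumerate(pair):
            u_site = rng.normal(0, cfg.site_sd, n_site)[site_idx]
            u_mut = rng.normal(0, cfg.mutualism_sd, n_mut)[mut_idx]
            mu = sum(beta(src, tgt) * values[src] for src in _PARENTS[tgt])
            values[tgt] = mu + u_site + u_mut + eps[:, j]

    df = pd.DataFrame(
        {
            "site_id": [f"S{i:02d}" for i in site_idx],
            "mutualism": [muts[m] for m in mut_idx],
            **{k: values[k] for k in ("MAT", "MAP", "LU", "FD_p", "FD_a", "niche_p", "niche_a")},
        }
    )
    truth = SyntheticTruth(
        config=asdict(cfg), seed=cfg.seed, coefficients={k: v for k, v in coef.items()}
    )
    return df, truth


def write_synthetic_dataset(outdir, config: ScenarioConfig | None = None) -> dict:
    """Simulate and write the CSV bundle plus the truth JSON."""
    cfg = config or ScenarioConfig()
    plants, animals, interactions, covariates, truth = simulate_dataset(cfg)
    paths = write_dataset(outdir, plants, animals, interactions, covariates)
    tp = Path(outdir) / "truth.json"
    truth.to_json(tp)
    paths["truth"] = tp
    return paths
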