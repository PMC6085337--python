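"""Functional diversity: Gower distances, PCoA and functional dispersion.

Functional dispersion (FDis) of a community is the abundance-weighted
mean distance of its species to the abundance-weighted centroid in a
trait space obtained by principal coordinates analysis (PCoA) of
range-standardised Gower distances.  Species abundances are the
marginal interaction totals of the site network, so FDis here measures
the functional spread of the species actually participating in the
network, weighted by how often they interact.

Gower distance between species i and j is the mean over traits of
|x_i − x_j| / range(trait); with quantitative traits it is bounded in
[0, 1] and reaches 1 only for two species at opposite extremes of every
trait's range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core_data import DataError, TraitTable, build_site_networks

logger = logging.getLogger(__name__)

TRAIT_SETS = ("all", "matching", "energy", "foraging")


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with entries in [0, 1]."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix must have zero diagonal")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise DataError("Gower distances must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def gower_distance(traits: pd.DataFrame | TraitTable, trait_subset="all") -> DistanceMatrix:
    """Range-standardised Gower distance over quantitative traits.

    d(i, j) = mean over traits of |x_i − x_j| / range; ranges are taken
    over the supplied table.  Zero-range traits are excluded from the
    mean (with a warning); missing values are handled by pairwise
    deletion.
    """
    if isinstance(traits, TraitTable):
        df = traits.subset_traits(trait_subset)
    else:
        df = traits
    if len(df) < 2:
        raise DataError("need at least two species for a distance matrix")
    X = df.to_numpy(dtype=float)
    rng = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    keep = rng > 0
    if not keep.any():
        raise DataError("all traits have zero range")
    if not keep.all():
        warnings.warn(
            f"excluding zero-range trait(s) {list(df.columns[~keep])} from Gower distance",
            stacklevel=2,
        )
    Xs = X[:, keep] / rng[keep]
    diff = np.abs(Xs[:, None, :] - Xs[None, :, :])  # n × n × t
    with np.errstate(invalid="ignore"):
        D = np.nanmean(diff, axis=2)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, list(df.index))


def pcoa(D: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Eigendecomposes the double-centred squared-distance matrix; axes
    with eigenvalue ≤ 1e−8 × the largest (including all negative axes)
    are dropped — no Cailliez/Lingoes correction, since range-standardised
    quantitative Gower distances are near-Euclidean for three traits.

    Returns (coordinates DataFrame, retained eigenvalues).
    """
    with warnings.catch_warnings():
        # skbio warns when negative eigenvalues are zeroed; that is our policy
        warnings.simplefilter("ignore")
        ord_res = _skbio_pcoa(_SkbioDM(D.values, ids=D.ids), method="eigh")
    eig = ord_res.eigvals.to_numpy()
    coords = ord_res.samples.to_numpy()
    keep = eig > 1e-8 * max(eig.max(), 1e-300)
    return pd.DataFrame(coords[:, keep], index=D.ids), eig[keep]


def functional_dispersion(coords: pd.DataFrame | np.ndarray, abundances) -> float:
    """Abundance-weighted mean distance to the abundance-weighted centroid.

    FDis = Σ a_i ‖x_i − c‖ / Σ a_i with c = Σ a_i x_i / Σ a_i.  Zero-
    abundance species contribute nothing; a single species gives 0.
    """
    X = coords.to_numpy(dtype=float) if isinstance(coords, pd.DataFrame) else np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    a = np.asarray(abundances, dtype=float)
    if len(a) != X.shape[0]:
        raise DataError("abundance vector length does not match coordinates")
    if np.any(a < 0):
        raise DataError("abundances must be non-negative")
    if a.sum() <= 0:
        raise DataError("abundances must not all be zero")
    w = a / a.sum()
    centroid = w @ X
    dist = np.linalg.norm(X - centroid, axis=1)
    return float(w @ dist)


def community_fd(traits, abundances: pd.Series, trait_subset="all") -> float:
    """Gower → PCoA → FDis for one community (species with abundance > 0)."""
    present = abundances[abundances > 0]
    if len(present) < 2:
        return 0.0
    df = traits.subset_traits(trait_subset) if isinstance(traits, TraitTable) else traits
    sub = df.loc[present.index]
    if sub.std(ddof=0).max() == 0:  # all species functionally identical
        return 0.0
    try:
        D = gower_distance(sub)
    except DataError:
        return 0.0
    coords, _ = pcoa(D)
    return functional_dispersion(coords, present.to_numpy())


def fd_pipeline(
    plants: TraitTable,
    animals: TraitTable,
    records: pd.DataFrame,
    trait_sets=("all", "matching", "energy", "foraging"),
    ranges: str = "global",
) -> pd.DataFrame:
    """Per-site functional dispersion of plants and animals.

    For each site network and trophic level, species abundances are the
    marginal interaction totals; traits are subset per ``trait_sets``
    and FDis computed in the PCoA trait space.  Sites with fewer than
    two interacting species at a level get FD = 0 and a flag.

    ``ranges`` controls where the Gower trait space is built:

    * ``"global"`` (default) — one distance matrix and PCoA embedding
      over all species of the mutualism × level, with ranges taken over
      that pool; every community is measured in the same trait space,
      so FDis responds to how widely a community spreads across the
      pool's trait axes.
    * ``"community"`` — Gower ranges and the embedding are recomputed
      within each community, making FDis a purely internal shape
      measure that is invariant to uniform scaling of the community's
      trait spread.

    Returns a tidy frame: site_id, mutualism, level, trait_set, fd,
    n_species, flagged.
    """
    if ranges not in ("global", "community"):
        raise ValueError(f"ranges must be 'global' or 'community', got {ranges!r}")
    rows = []
    for mutualism, sub in records.groupby("mutualism"):
        networks = build_site_networks(sub)
        for level, table in (("plant", plants), ("animal", animals)):
            margs = {
                site: (net.sum(axis=1) if level == "plant" else net.sum(axis=0))
                for site, net in networks.items()
            }
            margs = {s: m[m > 0] for s, m in margs.items()}
            pool = sorted(set().union(*(m.index for m in margs.values())))
            coords_by_set: dict[str, pd.DataFrame | None] = {}
            if ranges == "global":
                for ts in trait_sets:
                    df = table.subset_traits(ts).loc[pool]
                    try:
                        D = gower_distance(df)
                        coords_by_set[ts], _ = pcoa(D)
                    except DataError:
                        coords_by_set[ts] = None  # degenerate pool, FD := 0
            for site in networks:
                marg = margs[site]
                for ts in trait_sets:
                    flagged = len(marg) < 2
                    if flagged:
                        fd = 0.0
                    elif ranges == "global":
                        coords = coords_by_set[ts]
                        fd = (
                            0.0
                            if coords is None
                            else functional_dispersion(coords.loc[marg.index], marg.to_numpy())
                        )
                    else:
                        fd = community_fd(table, marg, ts)
                    rows.append(
                        {
                            "site_id": site,
                            "mutualism": mutualism,
                            "level": level,
                            "trait_set": ts,
                            "fd": fd,
                            "n_species": len(marg),
                            "flagged": flagged,
                        }
                    )
    return pd.DataFrame(rows)
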