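"""Domain containers, file I/O and data-preparation steps.

Holds the three tables every downstream analysis consumes:

* :class:`TraitTable` — one quantitative trait per functional role
  (``matching``, ``energy``, ``foraging``) for each species of one
  trophic level;
* :class:`InteractionData` — long-format interaction records, the
  binary metaweb ``L`` derived from them, and per-site weighted
  networks;
* :class:`SiteCovariates` — mean annual temperature (MAT, °C), mean
  annual precipitation (MAP, mm yr⁻¹), binary land use (LU, 0 =
  near-natural, 1 = anthropogenic), elevation (m a.s.l.) and habitat.

Also implements the small data-preparation regressions: climate
imputation from a cubic elevation polynomial plus habitat, log–log
allometric trait prediction, and taxonomic gap filling (genus →
family → order means).

Missing values are always encoded as NaN, never 0; species orderings
are lexicographic by id so every derived matrix is reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("matching", "energy", "foraging")
MUTUALISMS = ("bird-fruit", "bird-flower", "insect-flower")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (e.g. missing trait-type labels)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class TraitTable:
    """Species × trait matrix for one trophic level.

    Parameters
    ----------
    data:
        DataFrame indexed by ``species_id`` with exactly three numeric
        trait columns.  NaN marks a missing measurement.
    trait_types:
        Mapping trait column → functional role; each of ``matching``,
        ``energy`` and ``foraging`` must appear exactly once.
    trophic_level:
        ``"plant"`` or ``"animal"``.
    units:
        Optional mapping trait column → unit string (mm, g, m, counts, ...).
    """

    data: pd.DataFrame
    trait_types: dict[str, str]
    trophic_level: str
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trophic_level not in ("plant", "animal"):
            raise ConfigurationError(f"unknown trophic level {self.trophic_level!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated species_id: {dup}")
        if set(self.trait_types) != set(self.data.columns):
            raise ConfigurationError(
                "trait_types keys must match trait columns; "
                f"got {sorted(self.trait_types)} vs {sorted(self.data.columns)}"
            )
        roles = sorted(self.trait_types.values())
        if roles != sorted(TRAIT_TYPES):
            raise ConfigurationError(
                f"need exactly one trait per role {TRAIT_TYPES}, got {roles}"
            )
        self.data = self.data.sort_index()
        self.data.index.name = "species_id"

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def trait_for(self, role: str) -> str:
        """Name of the trait column with the given functional role."""
        for col, r in self.trait_types.items():
            if r == role:
                return col
        raise KeyError(role)

    def subset_traits(self, roles) -> pd.DataFrame:
        """Trait columns for a subset of roles ('all' or iterable of roles)."""
        if roles == "all" or roles is None:
            return self.data.copy()
        roles = [roles] if isinstance(roles, str) else list(roles)
        cols = [self.trait_for(r) for r in roles]
        return self.data[cols].copy()

    def with_data(self, data: pd.DataFrame) -> "TraitTable":
        return TraitTable(data, dict(self.trait_types), self.trophic_level, dict(self.units))


@dataclass
class InteractionData:
    """Long-format interaction records plus derived network views."""

    records: pd.DataFrame  # site_id, mutualism, plant_id, animal_id, count

    REQUIRED = ("site_id", "mutualism", "plant_id", "animal_id", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise DataError(f"interaction records lack columns {missing}")
        if (self.records["count"] < 0).any():
            raise DataError("negative interaction counts")

    def for_mutualism(self, mutualism: str) -> pd.DataFrame:
        sub = self.records[self.records["mutualism"] == mutualism]
        if sub.empty:
            raise DataError(f"no records for mutualism {mutualism!r}")
        return sub

    def metaweb(self, mutualism: str) -> pd.DataFrame:
        return build_metaweb(self.for_mutualism(mutualism))

    def site_networks(self, mutualism: str) -> dict[str, pd.DataFrame]:
        return build_site_networks(self.for_mutualism(mutualism))


@dataclass
class SiteCovariates:
    """Per-site abiotic covariates."""

    data: pd.DataFrame  # index site_id; MAT, MAP, LU, elevation, habitat

    REQUIRED = ("MAT", "MAP", "LU", "elevation", "habitat")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DataError(f"covariates lack columns {missing}")
        lu = self.data["LU"].dropna()
        if not lu.isin([0, 1]).all():
            raise DataError("LU must be binary 0/1")
        self.data = self.data.sort_index()
        self.data.index.name = "site_id"


# ---------------------------------------------------------------------------
# I/O


def read_trait_table(
    path, trait_type_map: dict[str, str], trophic_level: str, units: dict[str, str] | None = None
) -> TraitTable:
    """Read a trait CSV (``species_id`` column + one column per trait).

    Blank cells become NaN; a warning reports how many.  Unparseable
    numerics are reported by row and column.
    """
    df = pd.read_csv(path, dtype={"species_id": str})
    if "species_id" not in df.columns:
        raise DataError(f"{path}: no species_id column")
    df = df.set_index("species_id")
    bad = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for sp in df.index[coerced.isna() & df[col].notna()]:
            bad.append((sp, col, df.loc[sp, col]))
        df[col] = coerced
    if bad:
        raise DataError(f"{path}: unparseable numeric cells {bad}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        warnings.warn(f"{path}: {n_missing} missing trait value(s)", stacklevel=2)
    return TraitTable(df, trait_type_map, trophic_level, units or {})


def read_interactions(path) -> InteractionData:
    df = pd.read_csv(
        path, dtype={"site_id": str, "mutualism": str, "plant_id": str, "animal_id": str}
    )
    return InteractionData(df)


def read_covariates(path) -> SiteCovariates:
    df = pd.read_csv(path, dtype={"site_id": str, "habitat": str}).set_index("site_id")
    return SiteCovariates(df)


def write_dataset(
    outdir,
    plants: TraitTable,
    animals: TraitTable,
    interactions: InteractionData,
    covariates: SiteCovariates,
) -> dict[str, Path]:
    """Write the CSV dialects read back by the ``read_*`` functions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in (("plant_traits", plants), ("animal_traits", animals)):
        p = outdir / f"{name}.csv"
        table.data.to_csv(p)
        meta = pd.DataFrame(
            {
                "trait": list(table.trait_types),
                "trait_type": [table.trait_types[t] for t in table.trait_types],
                "units": [table.units.get(t, "") for t in table.trait_types],
            }
        )
        mp = outdir / f"{name}_meta.csv"
        meta.to_csv(mp, index=False)
        paths[name], paths[f"{name}_meta"] = p, mp
    p = outdir / "interactions.csv"
    interactions.records.to_csv(p, index=False)
    paths["interactions"] = p
    p = outdir / "covariates.csv"
    covariates.data.to_csv(p)
    paths["covariates"] = p
    return paths


# ---------------------------------------------------------------------------
# transformations


def sqrt_transform(table: TraitTable) -> TraitTable:
    """Element-wise square root of all traits (labels preserved).

    All traits are transformed uniformly, ratio traits included; ratios
    (Kipp's index, forewing index) are assumed to have been formed
    before this step.
    """
    if (table.data < 0).any().any():
        raise DataError("negative trait values; square-root transform undefined")
    return table.with_data(np.sqrt(table.data))


def build_metaweb(records: pd.DataFrame) -> pd.DataFrame:
    """Binary metaweb L: 1 iff a plant–animal pair interacted at least once.

    Rows are plants, columns animals, both sorted lexicographically;
    all-zero rows/columns cannot occur (every species listed appears in
    some positive record).
    """
    if records.empty:
        raise DataError("empty record set")
    if records["mutualism"].nunique() > 1:
        raise DataError("metaweb must be built from a single mutualism")
    pos = records[records["count"] > 0]
    if pos.empty:
        raise DataError("no positive interaction counts")
    L = (
        pos.groupby(["plant_id", "animal_id"])["count"]
        .sum()
        .unstack(fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return (L > 0).astype(int)


def build_site_networks(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-site weighted networks; cell = summed counts at that site."""
    out = {}
    for site, sub in records[records["count"] > 0].groupby("site_id"):
        net = (
            sub.groupby(["plant_id", "animal_id"])["count"]
            .sum()
            .unstack(fill_value=0)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        out[str(site)] = net
    return out


# ---------------------------------------------------------------------------
# imputation


def _cubic_habitat_design(elevation: pd.Series, habitat: pd.Series) -> pd.DataFrame:
    e = (elevation - elevation.mean()) / 1000.0  # centred km; conditioning only
    X = pd.DataFrame({"elev": e, "elev2": e**2, "elev3": e**3}, index=elevation.index)
    dummies = pd.get_dummies(habitat, prefix="habitat", drop_first=True, dtype=float)
    X = pd.concat([X, dummies], axis=1)
    X.insert(0, "const", 1.0)
    return X


def impute_climate(covariates: SiteCovariates) -> tuple[SiteCovariates, dict[str, float]]:
    """Fill missing MAT/MAP from OLS on elevation (cubic) + habitat.

    Fits, per climate variable, an ordinary-least-squares model with a
    third-order elevation polynomial and additive habitat indicators on
    the sites with observed values, and replaces missing values by the
    fitted predictions.  Observed values are never touched.

    Returns the completed covariates and the fit R² per variable.
    """
    df = covariates.data.copy()
    X_all = _cubic_habitat_design(df["elevation"], df["habitat"])
    r2: dict[str, float] = {}
    for var in ("MAT", "MAP"):
        obs = df[var].notna()
        if obs.all():
            continue
        if obs.sum() < 10:
            raise DataError(f"need >= 10 complete sites to impute {var}, have {int(obs.sum())}")
        X = X_all.loc[obs]
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            bad = _collinear_columns(X)
            raise DataError(f"rank-deficient design; collinear columns {bad}")
        fit = sm.OLS(df.loc[obs, var].astype(float), X.astype(float)).fit()
        r2[var] = float(fit.rsquared)
        pred = fit.predict(X_all.loc[~obs].astype(float))
        df.loc[~obs, var] = pred
        logger.info("imputed %d %s value(s), fit R^2 = %.4f", (~obs).sum(), var, r2[var])
    return SiteCovariates(df), r2


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (diagnostic only)."""
    A = X.to_numpy(dtype=float)
    full = np.linalg.matrix_rank(A)
    out = []
    for j, name in enumerate(X.columns):
        sub = np.delete(A, j, axis=1)
        if np.linalg.matrix_rank(sub) == full:
            out.append(name)
    return out


def impute_trait_allometric(predictor, intercept: float, slope: float) -> np.ndarray:
    """Predict a trait from a log–log allometric relation.

    prediction = exp(intercept + slope · ln(predictor)); e.g. bee body
    length from intertegular distance, or proboscis length from head
    width, with published intercept/slope pairs.
    """
    x = np.asarray(predictor, dtype=float)
    if np.any(x <= 0):
        raise DataError("allometric predictor must be strictly positive")
    return np.exp(intercept + slope * np.log(x))


def fit_allometry(predictor, response) -> tuple[float, float, float]:
    """Fit intercept/slope of ln(response) ~ ln(predictor) by least squares.

    Returns (intercept, slope, r²).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise DataError("allometric fit needs strictly positive values")
    X = sm.add_constant(np.log(x))
    fit = sm.OLS(np.log(y), X).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.rsquared)


def impute_trait_taxonomic(
    table: TraitTable, taxonomy: pd.DataFrame
) -> tuple[TraitTable, pd.DataFrame]:
    """Fill missing traits from taxonomic relatives (genus → family → order).

    ``taxonomy`` maps ``species_id`` (index or column) to ``genus``,
    ``family`` and ``order``.  Each missing cell is replaced by the mean
    of non-missing congeners, else confamilials, else members of the
    same order.  Returns the filled table and a provenance frame with
    one row per filled (or unresolvable) cell.
    """
    tax = taxonomy.set_index("species_id") if "species_id" in taxonomy.columns else taxonomy
    for col in ("genus", "family", "order"):
        if col not in tax.columns:
            raise ConfigurationError(f"taxonomy lacks column {col!r}")
    df = table.data.copy()
    prov = []
    for sp in df.index[df.isna().any(axis=1)]:
        if sp not in tax.index:
            raise DataError(f"species {sp!r} missing from taxonomy")
        for trait in df.columns[df.loc[sp].isna()]:
            filled = False
            for level in ("genus", "family", "order"):
                group = tax.index[tax[level] == tax.loc[sp, level]]
                vals = df.loc[df.index.intersection(group), trait].dropna()
                vals = vals.drop(index=sp, errors="ignore")
                if len(vals):
                    df.loc[sp, trait] = vals.mean()
                    prov.append({"species_id": sp, "trait": trait, "level": level})
                    filled = True
                    break
            if not filled:
                prov.append({"species_id": sp, "trait": trait, "level": "unresolved"})
                logger.warning("no relative with %s for species %s at any level", trait, sp)
    prov_df = pd.DataFrame(prov, columns=["species_id", "trait", "level"])
    return table.with_data(df), prov_df
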