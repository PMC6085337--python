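"""Degree-weighted RLQ co-inertia and fourth-corner permutation tests.

RLQ links three tables: plant traits R (m × p), animal traits Q (n × a)
and a binary metaweb L (m × n) of observed interactions.  The metaweb is
treated as a correspondence-analysis table: with P = L / L.sum(), row
weights r_i = Σ_j P_ij and column weights c_j = Σ_i P_ij are, for binary
L, proportional to species degree.  Traits are centred and scaled to
unit variance under these degree weights, and the cross-covariance
matrix

    Ω = R̃ᵀ (P − r cᵀ) Q̃            (p × a)

is decomposed by SVD.  Unit-norm coefficient vectors u_k (plants) and
v_k (animals) maximise the squared cross-covariance of the species
scores x_k = R̃ u_k and y_k = Q̃ v_k,

    (x_kᵀ P y_k)² = λ_k ,

subject to orthogonality across axes.  Statistical significance is
assessed by fourth-corner permutation tests: model 2 permutes plant
identities (rows of L), model 4 permutes animal identities (columns),
and model 6 combines both by taking the maximum p-value, the only
combination that controls the type-I error of the fourth-corner
problem.

Also provides Moran's exact Bernoulli probability for aggregating K
significant tests out of N trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import weighted_pearson, weighted_standardize
from .core_data import DataError, TraitTable

logger = logging.getLogger(__name__)

STATISTICS = ("sum_eigenvalues", "axis_correlation", "trait_axis_correlation")


@dataclass
class RLQResult:
    """Fitted RLQ ordination.

    ``eigenvalues`` are squared singular values of Ω (cross-covariance
    units²); ``plant_coefficients``/``animal_coefficients`` hold the
    unit-norm trait loadings U (p × k) and V (a × k); ``plant_scores``/
    ``animal_scores`` the species scores X = R̃U and Y = Q̃V; weights are
    the CA row/column weights (relative degree for binary L).
    """

    eigenvalues: np.ndarray
    plant_coefficients: pd.DataFrame
    animal_coefficients: pd.DataFrame
    plant_scores: pd.DataFrame
    animal_scores: pd.DataFrame
    row_weights: pd.Series
    col_weights: pd.Series
    percent_covariance: np.ndarray
    total_inertia: float

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


@dataclass
class FourthCornerResult:
    """Outcome of a fourth-corner permutation test."""

    statistic: str
    observed: float
    p_model2: float | None
    p_model4: float | None
    p_model6: float | None
    n_permutations: int
    seed: int
    alternative: str
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# core decomposition


def _as_matrix(traits, index) -> tuple[np.ndarray, list[str]]:
    df = traits.data if isinstance(traits, TraitTable) else traits
    missing = [s for s in index if s not in df.index]
    if missing:
        raise DataError(f"trait table lacks species {missing[:5]}{'...' if len(missing) > 5 else ''}")
    sub = df.loc[list(index)]
    if sub.isna().any().any():
        raise DataError("trait table contains missing values; impute first")
    return sub.to_numpy(dtype=float), list(sub.columns)


def _ca_parts(Lv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not np.isin(Lv, (0, 1)).all():
        raise DataError("L must be binary")
    if (Lv.sum(axis=1) == 0).any() or (Lv.sum(axis=0) == 0).any():
        raise DataError("L has zero-degree species; prune them before RLQ")
    P = Lv / Lv.sum()
    return P, P.sum(axis=1), P.sum(axis=0)


def _omega(Rt: np.ndarray, P: np.ndarray, r: np.ndarray, c: np.ndarray, Qt: np.ndarray) -> np.ndarray:
    return Rt.T @ (P - np.outer(r, c)) @ Qt


def rlq(R, L: pd.DataFrame, Q, k: int | None = None) -> RLQResult:
    """Fit the degree-weighted RLQ ordination.

    Parameters
    ----------
    R, Q:
        Plant and animal trait tables (``TraitTable`` or DataFrame
        indexed by species id); complete, already transformed.
    L:
        Binary metaweb DataFrame (plants × animals) without zero-degree
        species.
    k:
        Number of axes to keep (default ``min(p, a)``).

    Sign convention: per axis the coefficient of largest magnitude
    (over plant and animal loadings jointly) is made positive.
    """
    Lv = L.to_numpy(dtype=float)
    P, r, c = _ca_parts(Lv)
    Rv, r_traits = _as_matrix(R, L.index)
    Qv, q_traits = _as_matrix(Q, L.columns)
    Rt = weighted_standardize(Rv, r)
    Qt = weighted_standardize(Qv, c)
    Om = _omega(Rt, P, r, c, Qt)
    U, s, Vt = np.linalg.svd(Om, full_matrices=False)
    V = Vt.T
    kmax = min(len(s), Rv.shape[1], Qv.shape[1])
    k = kmax if k is None else min(k, kmax)
    U, V, s = U[:, :k], V[:, :k], s[:k]
    # deterministic sign: largest-|coefficient| entry per axis is positive
    for j in range(k):
        coefs = np.concatenate([U[:, j], V[:, j]])
        if coefs[np.argmax(np.abs(coefs))] < 0:
            U[:, j] *= -1
            V[:, j] *= -1
    lam = s**2
    total = float(np.sum(np.linalg.svd(Om, compute_uv=False) ** 2))
    axes = [f"axis{j + 1}" for j in range(k)]
    return RLQResult(
        eigenvalues=lam,
        plant_coefficients=pd.DataFrame(U, index=r_traits, columns=axes),
        animal_coefficients=pd.DataFrame(V, index=q_traits, columns=axes),
        plant_scores=pd.DataFrame(Rt @ U, index=L.index, columns=axes),
        animal_scores=pd.DataFrame(Qt @ V, index=L.columns, columns=axes),
        row_weights=pd.Series(r, index=L.index, name="weight"),
        col_weights=pd.Series(c, index=L.columns, name="weight"),
        percent_covariance=100.0 * lam / total,
        total_inertia=total,
    )


def select_axes(percent_covariance, coverage: float = 0.99, floor: int = 2) -> int:
    """Smallest number of leading axes reaching cumulative coverage.

    ``percent_covariance`` is in percent (sums to 100); default coverage
    0.99 with a floor of two axes (capped at the axes available).
    """
    pc = np.asarray(
        percent_covariance.percent_covariance
        if isinstance(percent_covariance, RLQResult)
        else percent_covariance,
        dtype=float,
    )
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    cum = np.cumsum(pc) / 100.0
    k_star = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    k_star = min(k_star, len(pc))
    return min(max(k_star, floor), len(pc))


def trait_axis_correlations(result: RLQResult, R, Q) -> pd.DataFrame:
    """Weighted Pearson correlations of each raw trait with the axis scores.

    Plant traits are correlated with the plant scores X under the row
    weights r, animal traits with Y under c.  Returns a tidy frame with
    columns level, trait, trait_type (if available), axis, r.
    """
    rows = []
    for level, traits, scores, w in (
        ("plant", R, result.plant_scores, result.row_weights),
        ("animal", Q, result.animal_scores, result.col_weights),
    ):
        mat, names = _as_matrix(traits, scores.index)
        types = traits.trait_types if isinstance(traits, TraitTable) else {}
        for t, name in enumerate(names):
            for j, axis in enumerate(scores.columns):
                rows.append(
                    {
                        "level": level,
                        "trait": name,
                        "trait_type": types.get(name, ""),
                        "axis": j + 1,
                        "r": weighted_pearson(mat[:, t], scores[axis].to_numpy(), w.to_numpy()),
                    }
                )
    return pd.DataFrame(rows)


def trait_type_summary(correlations: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Mean ± s.e.m. of |r| per trait type on one axis, across mutualisms."""
    sub = correlations[correlations["axis"] == axis].copy()
    sub["abs_r"] = sub["r"].abs()
    g = sub.groupby("trait_type")["abs_r"]
    return pd.DataFrame(
        {"mean_abs_r": g.mean(), "sem_abs_r": g.sem(ddof=1), "n": g.size()}
    ).reset_index()


# ---------------------------------------------------------------------------
# permutation inference


def _perm_pvalue(null_stats: np.ndarray, observed: float, alternative: str) -> float:
    """Add-one permutation p-value; ties count as extreme (conservative)."""
    null_stats = np.asarray(null_stats, dtype=float)
    if alternative == "greater":
        extreme = np.sum(null_stats >= observed)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(null_stats) >= np.abs(observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + extreme) / (len(null_stats) + 1))


def permutation_test(
    R,
    L: pd.DataFrame,
    Q,
    statistic: str = "sum_eigenvalues",
    n_perm: int = 9999,
    model: int = 6,
    seed: int = 0,
    axis: int = 1,
    trait: str | None = None,
    trait_level: str = "plant",
) -> FourthCornerResult:
    """Fourth-corner permutation test of plant–animal trait association.

    ``statistic``:

    * ``"sum_eigenvalues"`` — total RLQ cross-covariance Σλ = ‖Ω‖²_F,
      upper-tail test of global trait-space association;
    * ``"axis_correlation"`` — correlation (under P) between the fixed
      plant and animal scores of one RLQ ``axis``, two-sided;
    * ``"trait_axis_correlation"`` — fourth-corner correlation between a
      raw ``trait`` on one side and the other side's fixed axis scores,
      two-sided.

    Model 2 permutes plant identities (rows of L), model 4 animal
    identities (columns); model 6 runs both and reports the maximum of
    the two p-values.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if model not in (2, 4, 6):
        raise ValueError("model must be 2, 4 or 6")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    Lv = L.to_numpy(dtype=float)
    P, r, c = _ca_parts(Lv)
    Rv, _ = _as_matrix(R, L.index)
    Qv, _ = _as_matrix(Q, L.columns)
    Rt = weighted_standardize(Rv, r)
    Qt = weighted_standardize(Qv, c)

    if statistic == "sum_eigenvalues":
        alternative = "greater"
        # permuting species identities == permuting trait rows at fixed web
        MQ = (P - np.outer(r, c)) @ Qt  # m × a, fixed under row perms
        MR = Rt.T @ (P - np.outer(r, c))  # p × n, fixed under column perms

        def observed_stat() -> float:
            return float(np.sum((Rt.T @ MQ) ** 2))

        def stat_rows(perm: np.ndarray) -> float:
            Rp = weighted_standardize(Rv[perm], r)
            return float(np.sum((Rp.T @ MQ) ** 2))

        def stat_cols(perm: np.ndarray) -> float:
            Qp = weighted_standardize(Qv[perm], c)
            return float(np.sum((MR @ Qp) ** 2))

    else:
        alternative = "two-sided"
        fit = rlq(R, L, Q)
        if not 1 <= axis <= fit.k:
            raise ValueError(f"axis {axis} out of range (k = {fit.k})")
        if statistic == "axis_correlation":
            x = fit.plant_scores.iloc[:, axis - 1].to_numpy()
            y = fit.animal_scores.iloc[:, axis - 1].to_numpy()
        else:
            if trait is None:
                raise ValueError("trait_axis_correlation needs a trait name")
            if trait_level == "plant":
                tdf = R.data if isinstance(R, TraitTable) else R
                x = tdf.loc[L.index, trait].to_numpy(dtype=float)
                y = fit.animal_scores.iloc[:, axis - 1].to_numpy()
            else:
                tdf = Q.data if isinstance(Q, TraitTable) else Q
                y = tdf.loc[L.columns, trait].to_numpy(dtype=float)
                x = fit.plant_scores.iloc[:, axis - 1].to_numpy()

        def _corr(xv: np.ndarray, yv: np.ndarray) -> float:
            mx, my = r @ xv, c @ yv
            cov = xv @ P @ yv - mx * my
            vx = r @ (xv - mx) ** 2
            vy = c @ (yv - my) ** 2
            if vx <= 0 or vy <= 0:
                return np.nan
            return float(cov / np.sqrt(vx * vy))

        def observed_stat() -> float:
            return _corr(x, y)

        def stat_rows(perm: np.ndarray) -> float:
            return _corr(x[perm], y)

        def stat_cols(perm: np.ndarray) -> float:
            return _corr(x, y[perm])

    obs = observed_stat()
    rng = np.random.default_rng(seed)
    m, n = Lv.shape

    def run(side_stat, size) -> np.ndarray:
        out = np.empty(n_perm)
        n_degenerate = 0
        for i in range(n_perm):
            for _attempt in range(100):
                val = side_stat(rng.permutation(size))
                if np.isfinite(val):
                    break
                n_degenerate += 1
            else:  # pragma: no cover - pathological inputs only
                raise DataError("statistic degenerate on every resampled permutation")
            out[i] = val
        if n_degenerate:
            logger.info("resampled %d degenerate permutation(s)", n_degenerate)
        return out

    p2 = p4 = None
    if model in (2, 6):
        p2 = _perm_pvalue(run(stat_rows, m), obs, alternative)
    if model in (4, 6):
        p4 = _perm_pvalue(run(stat_cols, n), obs, alternative)
    p6 = max(p2, p4) if model == 6 else None
    return FourthCornerResult(
        statistic=statistic,
        observed=obs,
        p_model2=p2,
        p_model4=p4,
        p_model6=p6,
        n_permutations=n_perm,
        seed=seed,
        alternative=alternative,
        detail={"axis": axis, "trait": trait, "trait_level": trait_level},
    )


def moran_probability(N: int, K: int, alpha: float = 0.05) -> float:
    """Exact Bernoulli probability of K significant tests out of N trials.

    P = [N! / ((N−K)! K!)] α^K (1−α)^(N−K) — the point probability of
    observing exactly K rejections among N independent tests at level α,
    used to aggregate evidence across multiple fourth-corner tests.
    Computed in log space for numerical stability at large N.
    """
    if not 0 <= K <= N:
        raise ValueError("require 0 <= K <= N")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.exp(stats.binom.logpmf(K, N, alpha)))
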