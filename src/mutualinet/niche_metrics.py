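"""Interaction-niche metrics: effective partners e^H and specialisation d'.

Niche breadth of a species is the effective number of interaction
partners, e^H, the exponential of the Shannon entropy of its link
proportions; a species using four partners evenly has e^H = 4, a pure
specialist e^H = 1.

Niche partitioning is measured by the standardised Kullback–Leibler
specialisation d': the divergence d_i of a species' partner-use
proportions p'_ij from overall partner availability q_j (column
marginal totals), rescaled between the minimum and maximum divergence
achievable given the species' integer interaction total and the
partners' availabilities, so d' ∈ [0, 1].  The maximum is found by a
greedy integer reallocation that concentrates the species' interactions
on the least-available partners (capped by partner marginals); the
minimum by the integer allocation closest to proportional use
(largest-remainder rounding of the proportional target).  The greedy
maximum is a heuristic; it is verified against exhaustive enumeration
on small matrices in the test suite.

Network-level values are unweighted arithmetic means over the species
of one trophic level (an abundance-weighted mean is available).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._utils import zscale
from .core_data import SiteCovariates, TraitTable, build_site_networks
from .functional_diversity import fd_pipeline

logger = logging.getLogger(__name__)


def _level_matrix(network: pd.DataFrame, level: str) -> np.ndarray:
    """Counts with focal species on rows (plants: as-is, animals: transpose)."""
    A = network.to_numpy(dtype=float)
    if level == "animal":
        A = A.T
    elif level != "plant":
        raise ValueError(f"level must be 'plant' or 'animal', got {level!r}")
    return A


def effective_partners(network: pd.DataFrame, level: str, weighted_mean: bool = False):
    """Per-species effective number of partners e^H and the network mean.

    H_i is the Shannon entropy of species i's link proportions
    p_ij = a_ij / A_i; e^H_i ∈ [1, degree_i].  Species with zero total
    are excluded (logged).  Returns (per-species Series, mean).
    """
    A = _level_matrix(network, level)
    ids = network.index if level == "plant" else network.columns
    totals = A.sum(axis=1)
    if (totals == 0).any():
        logger.info("excluding %d zero-total species from e^H", int((totals == 0).sum()))
    keep = totals > 0
    P = A[keep] / totals[keep, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.sum(np.where(P > 0, P * np.log(P), 0.0), axis=1)
    eh = pd.Series(np.exp(H), index=ids[keep], name="e_H")
    w = totals[keep] / totals[keep].sum() if weighted_mean else None
    mean = float(np.average(eh.to_numpy(), weights=w))
    return eh, mean


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _d_max_alloc(total: int, avail: np.ndarray) -> np.ndarray:
    """Concentrate ``total`` units on least-available partners, capped by availability."""
    order = np.lexsort((np.arange(len(avail)), avail))  # stable: ties by index
    alloc = np.zeros(len(avail), dtype=float)
    remaining = float(total)
    for j in order:
        take = min(remaining, avail[j])
        alloc[j] = take
        remaining -= take
        if remaining <= 0:
            break
    if remaining > 0:  # availabilities exhausted; dump the rest on the rarest
        alloc[order[0]] += remaining
    return alloc


def _d_min_alloc(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation closest to the proportional target total·q."""
    target = total * q
    alloc = np.floor(target)
    short = int(round(total - alloc.sum()))
    if short > 0:
        frac = target - alloc
        order = np.lexsort((np.arange(len(q)), -frac))  # largest remainders first
        alloc[order[:short]] += 1
    return alloc


def kl_specialization(network: pd.DataFrame, level: str, weighted_mean: bool = False):
    """Per-species standardised Kullback–Leibler specialisation d'.

    Returns (per-species DataFrame with d, d_min, d_max, d_prime, and
    the network mean d').  Partner availability q_j is the partner
    marginal total over the whole network.  Degenerate species with
    d_max = d_min get d' = 0.
    """
    A = _level_matrix(network, level)
    ids = network.index if level == "plant" else network.columns
    totals = A.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        logger.info("excluding %d empty rows from d'", int((~keep).sum()))
    A = A[keep]
    totals = totals[keep]
    avail = A.sum(axis=0)  # partner marginal totals
    q = avail / avail.sum()
    rows = []
    for i in range(A.shape[0]):
        p = A[i] / totals[i]
        d = _kl(p, q)
        a_max = _d_max_alloc(totals[i], avail)
        d_max = _kl(a_max / a_max.sum(), q)
        a_min = _d_min_alloc(totals[i], q)
        d_min = _kl(a_min / a_min.sum(), q)
        if d_max - d_min > 1e-12:
            d_prime = (d - d_min) / (d_max - d_min)
        else:
            d_prime = 0.0
        rows.append({"d": d, "d_min": d_min, "d_max": d_max, "d_prime": float(np.clip(d_prime, 0, 1))})
    per = pd.DataFrame(rows, index=ids[keep])
    w = totals / totals.sum() if weighted_mean else None
    mean = float(np.average(per["d_prime"].to_numpy(), weights=w))
    return per, mean


def niche_table(records: pd.DataFrame, weighted_mean: bool = False) -> pd.DataFrame:
    """Mean e^H and d' per site × mutualism × trophic level (wide format)."""
    rows = []
    for mutualism, sub in records.groupby("mutualism"):
        for site, net in build_site_networks(sub).items():
            row = {"site_id": site, "mutualism": mutualism}
            for level, suffix in (("plant", "p"), ("animal", "a")):
                _, eh = effective_partners(net, level, weighted_mean)
                _, dp = kl_specialization(net, level, weighted_mean)
                row[f"eH_{suffix}"] = eh
                row[f"dprime_{suffix}"] = dp
            rows.append(row)
    return pd.DataFrame(rows)


def niche_pipeline(
    plants: TraitTable,
    animals: TraitTable,
    records: pd.DataFrame,
    covariates: SiteCovariates,
    trait_set: str = "all",
) -> pd.DataFrame:
    """Assemble the per-site metrics table feeding the structural models.

    One row per site × mutualism with FD_p, FD_a (for ``trait_set``),
    ln-transformed e^H_p/e^H_a, d'_p/d'_a, and MAT, MAP, LU.  Rows whose
    site lacks covariates are flagged and excluded from model input by
    :func:`zscale_metrics`.
    """
    fd = fd_pipeline(plants, animals, records, trait_sets=(trait_set,))
    fd_wide = fd.pivot_table(index=["site_id", "mutualism"], columns="level", values="fd").rename(
        columns={"plant": "FD_p", "animal": "FD_a"}
    )
    niche = niche_table(records).set_index(["site_id", "mutualism"])
    out = fd_wide.join(niche).reset_index()
    out["ln_eH_p"] = np.log(out["eH_p"])
    out["ln_eH_a"] = np.log(out["eH_a"])
    cov = covariates.data[["MAT", "MAP", "LU"]]
    out = out.merge(cov, left_on="site_id", right_index=True, how="left")
    out["complete"] = out[["MAT", "MAP", "LU"]].notna().all(axis=1)
    if not out["complete"].all():
        logger.warning(
            "%d row(s) missing covariates; flagged for exclusion", int((~out["complete"]).sum())
        )
    return out.sort_values(["mutualism", "site_id"]).reset_index(drop=True)


SEM_COLUMNS = ("MAT", "MAP", "LU", "FD_p", "FD_a", "ln_eH_p", "ln_eH_a", "dprime_p", "dprime_a")


def zscale_metrics(metrics: pd.DataFrame, columns=SEM_COLUMNS) -> pd.DataFrame:
    """z-scale model variables to zero mean, unit variance (complete rows only).

    Scaling is global across the pooled table (all mutualisms together),
    matching a model that pools mutualisms with a random factor.
    """
    out = metrics[metrics.get("complete", True) == True].copy()  # noqa: E712
    for col in columns:
        if col in out.columns:
            out[col] = zscale(out[col].to_numpy())
    return out
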