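"""Shared numerical helpers: weighted moments and seed management."""

from __future__ import annotations

import zlib

import numpy as np


def weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * np.asarray(x, dtype=float)) / np.sum(w))


def weighted_var(x: np.ndarray, w: np.ndarray) -> float:
    """Weighted variance with weights normalised to sum one (no dof correction)."""
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    x = np.asarray(x, dtype=float)
    m = np.sum(w * x)
    return float(np.sum(w * (x - m) ** 2))


def weighted_standardize(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Center and scale columns of ``X`` to zero mean, unit variance under ``w``.

    Raises ``ValueError`` on a zero-variance column (a constant trait carries
    no co-variance information and would produce a 0/0).
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    mu = w @ X
    Xc = X - mu
    var = w @ (Xc**2)
    if np.any(var <= 0):
        bad = np.where(var <= 0)[0].tolist()
        raise ValueError(f"zero weighted variance in column(s) {bad}")
    return Xc / np.sqrt(var)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation of ``x`` and ``y`` under weights ``w``."""
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    return float(cov / np.sqrt(vx * vy))


def zscale(x: np.ndarray) -> np.ndarray:
    """z-scale to zero mean and unit (ddof=1) standard deviation."""
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


def spawn_seed(seed: int, *labels) -> int:
    """Derive a stable sub-seed (< 2**31) from a global seed and labels.

    Uses CRC32 of the label strings so the derivation is identical across
    processes and sessions (``hash()`` is salted and would not be).
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(l).encode()) & 0x7FFFFFFF for l in labels]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))
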