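"""Calibration/validation partitioning.

SPXY (sample set partitioning based on joint x-y distances) is the field's
standard representative split for calibration work: Kennard-Stone selection
on a distance that combines spectral and response separation, each normalised
by its maximum,

    d(i, j) = dx(i, j) / max dx  +  dy(i, j) / max dy,

with Euclidean dx on the spectra and dy = |y_i - y_j|.  Selection seeds with
the most distant pair and then repeatedly adds the sample farthest (in
min-distance terms) from the selected set, so the calibration set spans the
hull of the data and the validation range nests inside it.

Kennard-Stone (x-only) and a seeded random split are provided as utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "spxy_split", "kennard_stone_split", "random_split"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive calibration/validation index partition."""

    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices)
        val = np.asarray(self.validation_indices)
        if np.intersect1d(cal, val).size:
            raise ValueError("calibration and validation sets overlap")


def calibration_size(n: int, ratio: float) -> int:
    """Round-half-up of n * ratio / (ratio + 1); e.g. 162 at 2:1 -> 108."""
    import math

    return int(math.floor(n * ratio / (ratio + 1.0) + 0.5))


def _kennard_stone_order(d: np.ndarray, n_select: int) -> list[int]:
    """Max-min selection on a precomputed distance matrix.

    Seeds with the pair attaining the maximum distance; ties broken by lowest
    sample index.  Deterministic.
    """
    n = d.shape[0]
    # argmax over the upper triangle, row-major => lowest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(d[iu]))
    first, second = int(iu[0][k]), int(iu[1][k])
    selected = [first, second]
    mask = np.ones(n, dtype=bool)
    mask[[first, second]] = False
    mind = np.minimum(d[first], d[second])
    while len(selected) < n_select:
        cand = np.where(mask, mind, -np.inf)
        j = int(np.argmax(cand))  # first max => lowest index on ties
        selected.append(j)
        mask[j] = False
        mind = np.minimum(mind, d[j])
    return selected


def spxy_split(X: np.ndarray, y: np.ndarray, ratio: float = 2.0) -> SplitResult:
    """SPXY split of N samples at calibration:validation ``ratio``.

    Raises
    ------
    ValueError
        If N < 3, y is constant, or all spectra are identical (the joint
        distance is then undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("SPXY needs at least 3 samples")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; joint x-y distance undefined")
    dx = squareform(pdist(X, metric="euclidean"))
    if dx.max() == 0:
        raise ValueError("all spectra identical; max spectral distance is zero")
    dy = np.abs(y[:, None] - y[None, :])
    d = dx / dx.max() + dy / dy.max()

    n_cal = calibration_size(n, ratio)
    n_cal = min(max(n_cal, 2), n - 1)
    cal = np.array(sorted(_kennard_stone_order(d, n_cal)), dtype=int)
    val = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, val, ratio)


def kennard_stone_split(X: np.ndarray, ratio: float = 2.0) -> SplitResult:
    """Classic Kennard-Stone on spectral distance only (test utility)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("Kennard-Stone needs at least 3 samples")
    d = squareform(pdist(X, metric="euclidean"))
    if d.max() == 0:
        raise ValueError("all spectra identical")
    n_cal = min(max(calibration_size(n, ratio), 2), n - 1)
    cal = np.array(sorted(_kennard_stone_order(d, n_cal)), dtype=int)
    return SplitResult(cal, np.setdiff1d(np.arange(n), cal), ratio)


def random_split(n: int, ratio: float, seed: int) -> SplitResult:
    """Seeded uniform random split (test utility)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = min(max(calibration_size(n, ratio), 1), n - 1)
    return SplitResult(np.sort(perm[:n_cal]), np.sort(perm[n_cal:]), ratio)
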