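"""Comparison wavelength selectors: FiPLS, BiPLS, UVE, MC-UVE, CARS.

Five established selectors used as yardsticks for the ensemble method.  All
of them share the PLS/cross-validation machinery from :mod:`nirselect.models`
so that comparisons differ only in selection logic, and every selector is a
deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models

__all__ = [
    "IntervalPartition",
    "StabilityTable",
    "partition_intervals",
    "fipls",
    "bipls",
    "uve",
    "uve_stability",
    "mc_uve",
    "mcuve_stability",
    "cars",
]


@dataclass(frozen=True)
class IntervalPartition:
    """Contiguous, disjoint, exhaustive split of M channels into k intervals.

    Sizes differ by at most one; the smaller intervals come first.
    """

    n_variables: int
    n_intervals: int
    boundaries: tuple[tuple[int, int], ...]  # half-open [start, end)

    def indices(self, interval: int) -> np.ndarray:
        start, end = self.boundaries[interval]
        return np.arange(start, end)


@dataclass
class StabilityTable:
    """Per-variable coefficient stability over resamples (UVE/MC-UVE)."""

    mean: np.ndarray
    sd: np.ndarray
    stability: np.ndarray
    is_noise: np.ndarray | None = None


def partition_intervals(M: int, k: int) -> IntervalPartition:
    """Split M variables into k near-equal contiguous intervals.

    With r = M mod k, the first k - r intervals hold floor(M/k) variables
    and the last r hold floor(M/k) + 1 (e.g. 4001 into 30 gives 19
    intervals of 133 then 11 of 134).
    """
    if not (1 <= k <= M):
        raise ValueError(f"need 1 <= k <= M, got k={k}, M={M}")
    base, r = divmod(M, k)
    sizes = [base] * (k - r) + [base + 1] * r
    bounds = []
    start = 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return IntervalPartition(M, k, tuple(bounds))


def _cv_rmse_pls(X, y, folds, seed, max_lv=models.DEFAULT_MAX_LV) -> float:
    return models.select_pls_lv(X, y, max_lv, folds, seed).best_rmsecv


def fipls(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 30,
    folds: int | str = 10,
    seed: int = 0,
    max_lv: int = models.DEFAULT_MAX_LV,
    return_trace: bool = False,
):
    """Forward interval PLS: greedily add the interval that most lowers
    RMSECV; stop when no addition improves it.  Returns channel indices
    (and the per-step RMSECV trace if ``return_trace``)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    part = partition_intervals(X.shape[1], k)
    chosen: list[int] = []
    remaining = list(range(k))
    best_err = np.inf
    trace: list[float] = []
    while remaining:
        scores = []
        for iv in remaining:
            cols = np.concatenate([part.indices(j) for j in chosen + [iv]])
            scores.append(_cv_rmse_pls(X[:, np.sort(cols)], y, folds, seed, max_lv))
        i_best = int(np.argmin(scores))
        if scores[i_best] >= best_err:
            break
        best_err = scores[i_best]
        trace.append(best_err)
        chosen.append(remaining.pop(i_best))
    if not chosen:  # first interval always enters (no-improvement on an empty model)
        chosen = [int(np.argmin(scores))]
        trace.append(float(np.min(scores)))
    selected = np.sort(np.concatenate([part.indices(j) for j in chosen]))
    return (selected, np.array(trace)) if return_trace else selected


def bipls(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 30,
    folds: int | str = 10,
    seed: int = 0,
    max_lv: int = models.DEFAULT_MAX_LV,
) -> np.ndarray:
    """Backward interval PLS: start from all intervals, greedily remove the
    interval whose removal most lowers RMSECV; stop when no removal helps."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    part = partition_intervals(X.shape[1], k)
    live = list(range(k))
    best_err = _cv_rmse_pls(X, y, folds, seed, max_lv)
    while len(live) > 1:
        scores = []
        for iv in live:
            keep = [j for j in live if j != iv]
            cols = np.sort(np.concatenate([part.indices(j) for j in keep]))
            scores.append(_cv_rmse_pls(X[:, cols], y, folds, seed, max_lv))
        i_best = int(np.argmin(scores))
        if scores[i_best] >= best_err:
            break
        best_err = scores[i_best]
        live.pop(i_best)
    return np.sort(np.concatenate([part.indices(j) for j in live]))


def _coefficient_stability(coefs: np.ndarray) -> StabilityTable:
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd > 0, mean / sd, 0.0)
    return StabilityTable(mean=mean, sd=sd, stability=c)


def uve_stability(
    X: np.ndarray,
    y: np.ndarray,
    folds: int | str = 10,
    seed: int = 0,
    max_lv: int = models.DEFAULT_MAX_LV,
    noise_scale: float = 1e-10,
) -> StabilityTable:
    """Leave-one-out coefficient stability with an appended noise block.

    M artificial noise columns (uniform [0, 1], scaled to ``noise_scale``
    of the spectral magnitude) are appended; PLS coefficients are collected
    over leave-one-out resamples and each variable's stability is
    c = mean/sd.  The first M entries are real variables, the rest noise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, 1.0, size=(n, m)) * noise_scale * np.mean(np.abs(X))
    Xa = np.hstack([X, noise])
    lv = models.select_pls_lv(X, y, max_lv, folds, seed).best_candidate
    coefs = np.empty((n, 2 * m))
    for i in range(n):
        keep = np.arange(n) != i
        coefs[i] = models.PLSModel(lv).fit(Xa[keep], y[keep]).coef_
    table = _coefficient_stability(coefs)
    table.is_noise = np.arange(2 * m) >= m
    return table


def uve(
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.9,
    folds: int | str = 10,
    seed: int = 0,
    max_lv: int = models.DEFAULT_MAX_LV,
    noise_scale: float = 1e-10,
    cutoff_mode: str = "max",
) -> np.ndarray:
    """Uninformative variable elimination.

    The cutoff is ``threshold * max|c|`` over the noise block of
    :func:`uve_stability` (``cutoff_mode="max"``) or the ``threshold``
    quantile of |c_noise| (``cutoff_mode="quantile"``); real variables
    with |c| > cutoff survive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    table = uve_stability(X, y, folds, seed, max_lv, noise_scale)
    c_real = np.abs(table.stability[:m])
    c_noise = np.abs(table.stability[m:])
    if cutoff_mode == "max":
        cutoff = threshold * c_noise.max()
    elif cutoff_mode == "quantile":
        cutoff = float(np.quantile(c_noise, threshold))
    else:
        raise ValueError("cutoff_mode must be 'max' or 'quantile'")
    return np.flatnonzero(c_real > cutoff)


def mcuve_stability(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 10,
    folds: int | str = 10,
    seed: int = 0,
    subsample: float = 0.8,
    max_lv: int = models.DEFAULT_MAX_LV,
) -> StabilityTable:
    """Coefficient stability over Monte-Carlo subsamples (no noise block)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    n_sub = max(2, int(round(subsample * n)))
    rng = np.random.default_rng(seed)
    lv = models.select_pls_lv(X, y, max_lv, folds, seed).best_candidate
    coefs = np.empty((runs, m))
    for r in range(runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        if np.ptp(y[rows]) == 0:
            rows = rng.choice(n, size=n_sub, replace=False)
        coefs[r] = models.PLSModel(lv).fit(X[rows], y[rows]).coef_
    return _coefficient_stability(coefs)


def mc_uve(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 10,
    eval_step: int = 10,
    folds: int | str = 10,
    seed: int = 0,
    subsample: float = 0.8,
    max_lv: int = models.DEFAULT_MAX_LV,
) -> np.ndarray:
    """Monte-Carlo UVE: stability from random subsamples, then a ranked
    forward sweep.

    Variables are ranked by |mean/sd| descending and the cross-validated
    error of the top-q sets evaluated at q = 1, 1+eval_step, ...; the best
    q wins.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[1]
    table = mcuve_stability(X, y, runs, folds, seed, subsample, max_lv)
    rank = np.argsort(-np.abs(table.stability), kind="stable")
    qs = list(range(1, m + 1, eval_step))
    if qs[-1] != m:
        qs.append(m)
    errs = [
        _cv_rmse_pls(X[:, np.sort(rank[:q])], y, folds, seed, max_lv) for q in qs
    ]
    q_best = qs[int(np.argmin(errs))]
    return np.sort(rank[:q_best])


def cars(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 500,
    folds: int | str = 5,
    seed: int = 0,
    subsample: float = 0.8,
    max_lv: int = models.DEFAULT_MAX_LV,
) -> np.ndarray:
    """Competitive adaptive reweighted sampling.

    Per run, a PLS model on a Monte-Carlo subsample of the live variables
    yields weights |b|; an exponentially decaying retention schedule (keep
    all M variables at run 1, keep 2 at the last run) sets the target
    count, and a weighted draw without replacement reduces the live set.
    The live set of the run with the minimum RMSECV is the answer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if runs < 2 or m < 3:
        raise ValueError("CARS needs runs >= 2 and at least 3 variables")
    rng = np.random.default_rng(seed)
    # two-point exponential through (1, 1) and (runs, 2/m)
    k = np.log(m / 2.0) / (runs - 1)
    a = np.exp(k)
    n_sub = max(2, int(round(subsample * n)))

    live = np.arange(m)
    best_err = np.inf
    best_live = live.copy()
    for i in range(1, runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        lv = int(min(max_lv, n_sub - 1, live.size))
        model = models.PLSModel(lv).fit(X[np.ix_(rows, live)], y[rows])
        weights = np.abs(model.coef_)
        err = _cv_rmse_pls(X[:, live], y, folds, seed, max_lv)
        if err < best_err:
            best_err = err
            best_live = live.copy()
        ratio = a * np.exp(-k * i)
        target = int(round(ratio * m))
        target = min(max(target, 2), live.size)
        if target == live.size:
            continue
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        p = weights / weights.sum()
        # weighted draw without replacement; zero-weight vars can never win
        nz = int(np.count_nonzero(p))
        if nz < target:
            keep_idx = np.argsort(-weights, kind="stable")[:target]
        else:
            keep_idx = rng.choice(live.size, size=target, replace=False, p=p)
        live = np.sort(live[keep_idx])
        if live.size <= 2:
            err = _cv_rmse_pls(X[:, live], y, folds, seed, max_lv)
            if err < best_err:
                best_err = err
                best_live = live.copy()
            break
    return np.sort(best_live)
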