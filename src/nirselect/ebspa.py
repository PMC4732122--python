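"""Bootstrap-ensemble SPA (BSPA) and the evaluated ensemble EBSPA.

Plain SPA is unstable on small calibration sets and, being unsupervised,
can select channels unrelated to the analyte.  The ensemble method attacks
both problems:

1. **BSPA** — draw T bootstrap resamples of the calibration set, run the
   full SPA search on each, keep each run's retained prefix F_i, and take
   the de-duplicated union F_B.
2. **Evaluation index** — score every union variable with
   ``w_i = alpha_i * p_i * b_i`` where ``alpha_i`` sums descending ordinal
   weights over the chains containing the variable (earlier-selected =>
   larger weight), ``p_i = sigma_i / mu_i`` is the spectral purity on the
   calibration matrix, and ``b_i`` is the absolute PLS regression
   coefficient of the variable in a model on the union set.
3. **Forward accumulation** — sort the union by w descending and grow a
   model one variable at a time; the prefix attaining the global minimum
   cross-validated RMSE is the final selection F_EB.

The whole procedure is a deterministic function of
``(X, y, T, H, model_spec, seed)``; per-iteration seeds are derived from
the master seed with a counter-based scheme so that raising T never
reshuffles earlier iterations (the union at T is always a subset of the
union at T+1 under the same master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .spa import SPAChain, spa_select

__all__ = [
    "EITable",
    "EnsembleSelection",
    "bootstrap_indices",
    "run_bspa",
    "compute_alpha",
    "compute_purity",
    "compute_b",
    "ebspa_select",
]

_PURITY_EPS = 1e-8


@dataclass
class EITable:
    """Evaluation-index components for every union-set variable."""

    variables: np.ndarray  # channel indices (union set, ascending)
    alpha: np.ndarray
    purity: np.ndarray
    b: np.ndarray
    w: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.variables = np.asarray(self.variables, dtype=int)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.purity = np.asarray(self.purity, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if np.any(self.alpha < 1):
            raise ValueError("every union-set member must have alpha >= 1")
        self.w = self.alpha * self.purity * self.b


@dataclass
class EnsembleSelection:
    """Full record of one EBSPA run."""

    chains: list[SPAChain]
    union: np.ndarray
    ei: EITable
    sorted_order: np.ndarray  # union variables by w descending
    accumulation_rmsecv: np.ndarray
    final_selected: np.ndarray  # F_EB: chosen prefix of sorted_order

    def __post_init__(self) -> None:
        if self.final_selected.size > self.union.size:
            raise ValueError("final selection cannot exceed the union set")
        if not np.array_equal(
            self.final_selected, self.sorted_order[: self.final_selected.size]
        ):
            raise ValueError("final selection must be a prefix of the sorted order")

    @property
    def n_selected(self) -> int:
        return int(self.final_selected.size)


def _iteration_seed(seed: int, iteration: int, attempt: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(iteration, attempt))


def bootstrap_indices(n: int, seed) -> np.ndarray:
    """n draws with replacement from 0..n-1, reproducible from ``seed``."""
    if n < 2:
        raise ValueError("need n >= 2 samples to bootstrap")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=n)


def run_bspa(
    X: np.ndarray,
    y: np.ndarray,
    T: int = 10,
    H: int = 20,
    model_spec: models.ModelSpec | None = None,
    folds: int | str = 10,
    seed: int = 0,
    k0_candidates: np.ndarray | None = None,
) -> tuple[list[SPAChain], np.ndarray]:
    """T bootstrap SPA runs and the de-duplicated union of their selections.

    Each iteration resamples the calibration rows with replacement (same
    size as the original set), runs the full ``spa_select`` search on the
    resample, and keeps the chosen prefix F_i; variables beyond h are the
    invalid tail and are dropped.  A resample with constant y is redrawn
    with the next derived seed.  Channel indices refer to the original
    matrix throughout.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if T < 1:
        raise ValueError("T must be >= 1")
    n = X.shape[0]
    chains: list[SPAChain] = []
    for i in range(T):
        for attempt in range(100):
            ss = _iteration_seed(seed, i, attempt)
            idx = bootstrap_indices(n, ss)
            if np.ptp(y[idx]) > 0:
                break
        else:  # pragma: no cover - requires pathological y
            raise ValueError("could not draw a bootstrap set with non-constant y")
        inner_seed = int(ss.generate_state(1)[0] % (2**31))
        chain = spa_select(
            X[idx],
            y[idx],
            H=H,
            model_spec=model_spec,
            folds=folds,
            seed=inner_seed,
            k0_candidates=k0_candidates,
        )
        chains.append(chain)
    union = np.unique(np.concatenate([c.selected for c in chains]))
    return chains, union


def compute_alpha(
    chains: list[SPAChain], scheme: str = "h", H: int | None = None
) -> dict[int, float]:
    """Summed ordinal weights per variable over all chains containing it.

    Within a chain of retained length h, the j-th selected variable
    (j = 1 first) receives weight ``h - j + 1`` (scheme ``"h"``, default) or
    ``H - j + 1`` (scheme ``"H"``); a variable's alpha is the sum over
    chains.  Variables absent from every chain do not appear.
    """
    if not chains:
        raise ValueError("chains must be nonempty")
    if scheme not in ("h", "H"):
        raise ValueError("scheme must be 'h' or 'H'")
    if scheme == "H" and H is None:
        raise ValueError("scheme 'H' needs the maximum chain length H")
    alpha: dict[int, float] = {}
    for chain in chains:
        top = chain.h if scheme == "h" else H
        for j, var in enumerate(chain.selected, start=1):
            alpha[int(var)] = alpha.get(int(var), 0.0) + (top - j + 1)
    return alpha


def compute_purity(X_cal: np.ndarray, variables: np.ndarray | None = None) -> np.ndarray:
    """Spectral purity p_i = sd_i / |mean_i| on the calibration matrix.

    Sample (n-1) standard deviation over samples; the mean is guarded as
    ``max(|mean|, 1e-8)`` and the sign discarded so p_i >= 0 (preprocessed
    variables can have near-zero means).
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    cols = X_cal if variables is None else X_cal[:, np.asarray(variables, dtype=int)]
    sd = cols.std(axis=0, ddof=1)
    mu = np.maximum(np.abs(cols.mean(axis=0)), _PURITY_EPS)
    return sd / mu


def compute_b(
    X_cal: np.ndarray,
    y: np.ndarray,
    variables: np.ndarray,
    folds: int | str = 10,
    seed: int = 0,
    max_lv: int = models.DEFAULT_MAX_LV,
) -> np.ndarray:
    """|regression coefficient| per union variable from one PLS fit.

    A single PLS model (latent variables chosen by cross-validation) is fit
    on the calibration matrix restricted to the union set; the absolute
    coefficients are returned in the original variable space, aligned with
    ``variables``.
    """
    variables = np.asarray(variables, dtype=int)
    Xu = np.atleast_2d(np.asarray(X_cal, dtype=float))[:, variables]
    y = np.asarray(y, dtype=float).ravel()
    lv = models.select_pls_lv(Xu, y, max_lv, folds, seed).best_candidate
    model = models.PLSModel(lv).fit(Xu, y)
    return np.abs(model.coef_)


def ebspa_select(
    X: np.ndarray,
    y: np.ndarray,
    T: int = 10,
    H: int = 20,
    model_spec: models.ModelSpec | None = None,
    folds: int | str = 10,
    seed: int = 0,
    k0_candidates: np.ndarray | None = None,
    alpha_scheme: str = "h",
) -> EnsembleSelection:
    """Full EBSPA: bootstrap ensemble, evaluation index, forward accumulation.

    The union variables are sorted by w descending (ties: higher alpha,
    then lower channel index) and the cross-validated PLS error of every
    sorted prefix is computed on the original calibration set; the final
    selection is the prefix at the global minimum (ties: smaller prefix).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    spec = model_spec or models.ModelSpec()
    chains, union = run_bspa(
        X, y, T=T, H=H, model_spec=spec, folds=folds, seed=seed,
        k0_candidates=k0_candidates,
    )
    alpha_map = compute_alpha(chains, scheme=alpha_scheme, H=H)
    alpha = np.array([alpha_map[int(v)] for v in union], dtype=float)
    purity = compute_purity(X, union)
    b = compute_b(X, y, union, folds=folds, seed=seed, max_lv=spec.max_lv)
    ei = EITable(variables=union, alpha=alpha, purity=purity, b=b)

    # w descending; ties -> higher alpha, then lower channel index
    order = np.lexsort((ei.variables, -ei.alpha, -ei.w))
    sorted_vars = ei.variables[order]

    fold_id = models.make_folds(X.shape[0], folds, seed)
    acc_spec = spec if spec.kind == "pls" else models.ModelSpec(kind="pls", max_lv=spec.max_lv)
    curve, _ = models.rmsecv_prefix_curve(X[:, sorted_vars], y, fold_id, acc_spec)
    n_final = int(np.argmin(curve)) + 1  # first min => smaller prefix on ties
    return EnsembleSelection(
        chains=chains,
        union=union,
        ei=ei,
        sorted_order=sorted_vars,
        accumulation_rmsecv=curve,
        final_selected=sorted_vars[:n_final],
    )
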