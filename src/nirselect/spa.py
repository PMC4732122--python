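"""Successive projections algorithm (SPA).

SPA is a greedy forward wavelength selector that minimises collinearity: at
each step every remaining spectral channel is projected onto the orthogonal
complement of the channels already selected, and the channel with the
largest residual norm is taken next.  The implementation maintains running
residual columns — projecting against only the most recently selected
(already projected) column each step — which is algebraically equivalent to
full re-orthogonalisation against the selected span but costs O(H*N*M)
instead of O(H^2*N*M); the test suite checks the equivalence against an
explicit Gram-Schmidt oracle.

SPA itself is unsupervised; the search over the starting channel k0 and the
chain length h is driven by cross-validated regression error (RMSECV), and
the (k0, h) pair attaining the global minimum is the final choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from ._kernels import spa_chain_kernel

__all__ = ["SPAChain", "project_out", "spa_chain", "spa_select"]

_TOL = 1e-12


@dataclass
class SPAChain:
    """One SPA run: start channel, selection order, error curve, chosen length."""

    k0: int
    order: np.ndarray
    rmsecv_by_length: np.ndarray
    h: int

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if self.order.size and self.order[0] != self.k0:
            raise ValueError("order[0] must equal k0")
        if len(set(self.order.tolist())) != self.order.size:
            raise ValueError("selected indices must be distinct")
        if not (1 <= self.h <= self.order.size):
            raise ValueError("h must lie in 1..len(order)")

    @property
    def selected(self) -> np.ndarray:
        """The retained prefix: the first h selected channels."""
        return self.order[: self.h]

    @property
    def min_rmsecv(self) -> float:
        return float(self.rmsecv_by_length[self.h - 1])


def project_out(v: np.ndarray, basis_vector: np.ndarray) -> np.ndarray:
    """Project ``v`` onto the orthogonal complement of ``basis_vector``.

    Applies ``P = I - x x^T / (x^T x)``; the output is orthogonal to the
    basis vector.  A zero basis vector is rejected.
    """
    v = np.asarray(v, dtype=float)
    x = np.asarray(basis_vector, dtype=float)
    nrm2 = float(x @ x)
    if nrm2 < _TOL * _TOL:
        raise ValueError("basis vector has (near-)zero norm")
    return v - x * (float(x @ v) / nrm2)


def spa_chain(X: np.ndarray, k0: int, H: int) -> np.ndarray:
    """Greedy projection chain of up to H channels starting at column k0.

    Stops early when every remaining residual norm falls below 1e-12 (the
    remaining channels are then numerically in the span of the selection).
    Ties in the argmax are broken by lowest channel index.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    n, m = X.shape
    if not (0 <= k0 < m):
        raise ValueError(f"k0 {k0} out of range for {m} channels")
    H = int(min(H, n, m))
    if H < 1:
        raise ValueError("H must be >= 1")
    order, length = spa_chain_kernel(X, int(k0), H, _TOL)
    return order[:length].copy()


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    H: int = 20,
    model_spec: models.ModelSpec | None = None,
    folds: int | str = 10,
    seed: int = 0,
    k0_candidates: np.ndarray | None = None,
) -> SPAChain:
    """Full SPA search: best (k0, h) by minimum cross-validated RMSE.

    For every candidate start channel the projection chain is built and the
    RMSECV of each prefix length 1..H is computed with the given model
    (default PLS, latent variables chosen by the same CV).  The global
    minimum wins; ties prefer the smaller h, then the smaller k0.  Channels
    with zero variance are excluded from the candidate starts.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    spec = model_spec or models.ModelSpec()
    H = int(min(H, n - 1, m))
    if H < 1:
        raise ValueError("not enough samples/channels for H >= 1")
    if k0_candidates is None:
        k0_candidates = np.arange(m)
    k0_candidates = np.asarray(k0_candidates, dtype=int)
    variances = X.var(axis=0)
    k0_candidates = np.array(
        [k for k in k0_candidates if variances[k] > _TOL], dtype=int
    )
    if k0_candidates.size == 0:
        raise ValueError("no k0 candidate has nonzero variance")

    fold_id = models.make_folds(n, folds, seed)
    best: tuple[float, int, int] | None = None  # (rmsecv, h, k0)
    best_chain: tuple[np.ndarray, np.ndarray] | None = None
    for k0 in k0_candidates:
        order = spa_chain(X, int(k0), H)
        curve, _ = models.rmsecv_prefix_curve(X[:, order], y, fold_id, spec)
        h_local = int(np.argmin(curve)) + 1  # first min => smaller h on ties
        key = (float(curve[h_local - 1]), h_local, int(k0))
        if best is None or key < best:
            best = key
            best_chain = (order, curve)
    order, curve = best_chain
    return SPAChain(k0=int(order[0]), order=order, rmsecv_by_length=curve, h=best[1])
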