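"""Regression backends, cross-validation harness, and error metrics.

Three predictor families share one fit/predict/coefficients contract:

* ``MLRModel`` — ordinary least squares with intercept (requires more
  samples than variables and full column rank);
* ``PLSModel`` — PLS1 via NIPALS on column-centred data, coefficients
  returned in the original variable space;
* ``LSSVMModel`` — least-squares SVM regression with an RBF kernel
  ``K(x, z) = exp(-||x - z||^2 / sigma2)``, solved as a single linear
  system with ridge term ``I / gamma``.

Cross-validation refits the whole model per fold (centring statistics and
hyperparameters never leak across folds).  The fold partition is a function
of ``(n, folds, seed)`` only; ``folds="loo"`` gives n singleton folds.
Metric definitions (RMSE, Pearson r) live here and are used unchanged by
every selector in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._kernels import pls1_cv_sse, pls1_prefix_sse

__all__ = [
    "ModelSpec",
    "CVResult",
    "MLRModel",
    "PLSModel",
    "LSSVMModel",
    "rmse",
    "pearson_r",
    "make_folds",
    "select_pls_lv",
    "tune_lssvm",
    "cross_validate",
    "fit_model",
    "rmsecv_prefix_curve",
]

DEFAULT_MAX_LV = 15
_LSSVM_GAMMAS = tuple(float(g) for g in np.logspace(-2, 4, 7))
_LSSVM_SIGMA2S = tuple(float(s) for s in np.logspace(-4, 2, 7))


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root-mean-square error."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pearson_r(pred: np.ndarray, obs: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    return float(np.corrcoef(pred, obs)[0, 1])


def make_folds(n: int, folds: int | str, seed: int = 0) -> np.ndarray:
    """Deterministic fold assignment of n samples.

    Returns an integer array ``fold_id`` of length n.  ``folds="loo"``
    assigns each sample its own fold (order-independent).
    """
    if folds == "loo":
        return np.arange(n, dtype=np.int64)
    folds = int(folds)
    if folds < 2:
        raise ValueError("folds must be >= 2 or 'loo'")
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=np.int64)
    fold_id[perm] = np.arange(n) % folds
    return fold_id


def n_folds_of(fold_id: np.ndarray) -> int:
    return int(fold_id.max()) + 1


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a regression backend.

    ``n_latent=None`` (PLS) or ``gamma/sigma2=None`` (LS-SVM) means the
    hyperparameter is chosen by cross-validation at fit time.
    """

    kind: str = "pls"
    max_lv: int = DEFAULT_MAX_LV
    n_latent: int | None = None
    gamma: float | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mlr", "pls", "lssvm"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class CVResult:
    """Per-candidate RMSECV values and the chosen candidate."""

    candidates: list
    rmsecv: np.ndarray
    fold_id: np.ndarray
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        self.best_index = int(np.argmin(self.rmsecv))

    @property
    def best_candidate(self):
        return self.candidates[self.best_index]

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.best_index])


class MLRModel:
    """Ordinary least squares with intercept."""

    kind = "mlr"

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLRModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(
                f"MLR needs more samples than variables + 1: n={n}, p={p}"
            )
        A = np.column_stack([np.ones(n), X])
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p + 1:
            raise ValueError(
                f"design matrix rank deficient: rank {rank} < {p + 1} (n={n}, p={p})"
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("predict before fit")
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef_ + self.intercept_


class PLSModel:
    """PLS1 regression (NIPALS) with a fixed number of latent variables.

    If the residual X norm collapses before ``n_components`` directions are
    extracted the model keeps the achieved count and records it in
    ``n_components_``.
    """

    kind = "pls"

    def __init__(self, n_components: int) -> None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(n_components)
        self.n_components_: int | None = None
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        a_req = min(self.n_components, n - 1, p)
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        E = X - x_mean
        f = y - y_mean
        W = np.zeros((p, a_req))
        P = np.zeros((p, a_req))
        q = np.zeros(a_req)
        a_got = 0
        for a in range(a_req):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                break
            w /= nw
            t = E @ w
            tt = t @ t
            if tt < 1e-24:
                break
            P[:, a] = E.T @ t / tt
            q[a] = (f @ t) / tt
            W[:, a] = w
            E -= np.outer(t, P[:, a])
            f = f - q[a] * t
            a_got += 1
        if a_got == 0:
            # y uncorrelated with X: intercept-only model
            self.coef_ = np.zeros(p)
        else:
            Wa, Pa, qa = W[:, :a_got], P[:, :a_got], q[:a_got]
            self.coef_ = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        self.n_components_ = a_got
        self.intercept_ = float(y_mean - x_mean @ self.coef_)
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("predict before fit")
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef_ + self.intercept_


class LSSVMModel:
    """LS-SVM regression with RBF kernel and ridge term I/gamma."""

    kind = "lssvm"

    def __init__(self, gamma: float, sigma2: float) -> None:
        if gamma <= 0 or sigma2 <= 0:
            raise ValueError("gamma and sigma2 must be > 0")
        self.gamma = float(gamma)
        self.sigma2 = float(sigma2)
        self.alpha_: np.ndarray | None = None
        self.bias_: float | None = None
        self.X_train_: np.ndarray | None = None
        self.fitted = False

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return np.exp(-cdist(A, B, "sqeuclidean") / self.sigma2)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSSVMModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        K = self._kernel(X, X) + np.eye(n) / self.gamma
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K
        rhs = np.concatenate([[0.0], y])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"LS-SVM system singular (cond={np.linalg.cond(A):.3e}); "
                "increase gamma or sigma2"
            ) from exc
        self.bias_ = float(sol[0])
        self.alpha_ = sol[1:]
        self.X_train_ = X
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("predict before fit")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._kernel(X, self.X_train_) @ self.alpha_ + self.bias_


def _pls_cv_rmsecv(X, y, fold_id, max_lv) -> np.ndarray:
    """RMSECV per latent-variable count 1..max_lv (pooled out-of-fold)."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    sse = pls1_cv_sse(X, y, fold_id, n_folds_of(fold_id), int(max_lv))
    return np.sqrt(sse / y.size)


def select_pls_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int | None = None,
    folds: int | str = 10,
    seed: int = 0,
) -> CVResult:
    """Choose the PLS latent-variable count minimising RMSECV over 1..max_lv."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if max_lv is None:
        max_lv = DEFAULT_MAX_LV
    max_lv = int(min(max_lv, n - 1, p))
    fold_id = make_folds(n, folds, seed)
    curve = _pls_cv_rmsecv(X, y, fold_id, max_lv)
    return CVResult(list(range(1, max_lv + 1)), curve, fold_id)


def tune_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    gammas=_LSSVM_GAMMAS,
    sigma2s=_LSSVM_SIGMA2S,
    folds: int | str = "loo",
    seed: int = 0,
) -> CVResult:
    """Exhaustive (gamma, sigma2) grid search by cross-validated RMSE.

    Leave-one-out by default; the grid minimum wins, ties to the first grid
    point in row-major (gamma-major) order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    fold_id = make_folds(X.shape[0], folds, seed)
    nf = n_folds_of(fold_id)
    candidates = [(float(g), float(s)) for g in gammas for s in sigma2s]
    scores = np.empty(len(candidates))
    for ci, (g, s) in enumerate(candidates):
        sse = 0.0
        for f in range(nf):
            tr = fold_id != f
            te = ~tr
            model = LSSVMModel(g, s).fit(X[tr], y[tr])
            pred = model.predict(X[te])
            sse += float(np.sum((pred - y[te]) ** 2))
        scores[ci] = np.sqrt(sse / y.size)
    return CVResult(candidates, scores, fold_id)


def cross_validate(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, folds: int | str = 10, seed: int = 0
) -> CVResult:
    """RMSECV of a model spec; candidates depend on the backend.

    For PLS the candidates are latent-variable counts; for MLR and a fully
    specified LS-SVM there is a single candidate; an LS-SVM with unset
    hyperparameters is tuned on its grid.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if spec.kind == "pls":
        if spec.n_latent is not None:
            lv = int(min(spec.n_latent, n - 1, X.shape[1]))
            fold_id = make_folds(n, folds, seed)
            curve = _pls_cv_rmsecv(X, y, fold_id, lv)
            return CVResult([lv], curve[-1:], fold_id)
        return select_pls_lv(X, y, spec.max_lv, folds, seed)
    if spec.kind == "mlr":
        fold_id = make_folds(n, folds, seed)
        nf = n_folds_of(fold_id)
        sse = 0.0
        for f in range(nf):
            tr = fold_id != f
            model = MLRModel().fit(X[tr], y[tr])
            pred = model.predict(X[~tr])
            sse += float(np.sum((pred - y[~tr]) ** 2))
        return CVResult(["mlr"], np.array([np.sqrt(sse / n)]), fold_id)
    if spec.kind == "lssvm":
        if spec.gamma is not None and spec.sigma2 is not None:
            return tune_lssvm(X, y, [spec.gamma], [spec.sigma2], folds, seed)
        return tune_lssvm(X, y, folds=folds, seed=seed)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def fit_model(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, folds: int | str = 10, seed: int = 0
):
    """Fit a backend, resolving unset hyperparameters by cross-validation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if spec.kind == "mlr":
        return MLRModel().fit(X, y)
    if spec.kind == "pls":
        if spec.n_latent is not None:
            lv = int(spec.n_latent)
        else:
            lv = select_pls_lv(X, y, spec.max_lv, folds, seed).best_candidate
        return PLSModel(lv).fit(X, y)
    if spec.kind == "lssvm":
        if spec.gamma is not None and spec.sigma2 is not None:
            g, s = spec.gamma, spec.sigma2
        else:
            g, s = tune_lssvm(X, y, folds="loo").best_candidate
        return LSSVMModel(g, s).fit(X, y)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def rmsecv_prefix_curve(
    X_ordered: np.ndarray,
    y: np.ndarray,
    fold_id: np.ndarray,
    spec: ModelSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RMSECV for every column prefix of ``X_ordered``.

    The columns of ``X_ordered`` are candidate variables in selection order;
    the curve entry ``t-1`` is the cross-validated error of the model using
    the first ``t`` columns.  For PLS the latent-variable count for each
    prefix is itself chosen by the same cross-validation (minimum over
    1..max_lv); the chosen counts are returned alongside the curve.  For MLR
    prefixes too wide for the training folds get ``inf``.
    """
    spec = spec or ModelSpec()
    Xo = np.ascontiguousarray(np.atleast_2d(X_ordered), dtype=float)
    y = np.ascontiguousarray(np.asarray(y, dtype=float).ravel())
    n, H = Xo.shape
    nf = n_folds_of(fold_id)
    if spec.kind == "pls":
        max_lv = int(min(spec.max_lv, n - 1, H))
        sse = pls1_prefix_sse(Xo, y, fold_id, nf, max_lv)
        curves = np.sqrt(sse / n)
        best_lv = np.argmin(curves, axis=1) + 1
        return curves.min(axis=1), best_lv
    if spec.kind == "mlr":
        curve = np.full(H, np.inf)
        for t in range(1, H + 1):
            sse = 0.0
            ok = True
            for f in range(nf):
                tr = fold_id != f
                try:
                    model = MLRModel().fit(Xo[tr][:, :t], y[tr])
                except ValueError:
                    ok = False
                    break
                pred = model.predict(Xo[~tr][:, :t])
                sse += float(np.sum((pred - y[~tr]) ** 2))
            if ok:
                curve[t - 1] = np.sqrt(sse / n)
        return curve, np.ones(H, dtype=np.int64)
    raise ValueError("prefix curves support 'pls' and 'mlr' backends")
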