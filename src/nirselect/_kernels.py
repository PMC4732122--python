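"""Compiled numeric kernels.

The SPA and EBSPA searches evaluate a cross-validated PLS error at every
(starting channel, prefix length) pair — tens of thousands of tiny PLS1
fits per run — so the inner loops are compiled with numba.  Each kernel has
a straightforward numpy twin in the test suite (and sklearn's PLSRegression
as an independent oracle), which the tests check against these fast paths.

All PLS here is PLS1 via NIPALS on column-centred X and centred y.  Test-set
predictions are produced by propagating the test spectra through the same
deflation sequence, which is algebraically identical to applying the
regression-coefficient form.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["spa_chain_kernel", "pls1_prefix_sse", "pls1_cv_sse"]


@njit(cache=True)
def spa_chain_kernel(X, k0, H, tol):
    """Greedy successive-projections chain starting at column ``k0``.

    Maintains running residual columns: at each step every remaining column
    is projected onto the orthogonal complement of the last selected
    (already projected) column, and the column with the largest residual
    norm is taken next (ties -> lowest index).  Stops early when all
    residual norms fall below ``tol``.

    Returns (order, length): ``order`` has size H, only ``order[:length]``
    is meaningful.
    """
    N, M = X.shape
    R = X.copy()
    order = np.empty(H, dtype=np.int64)
    taken = np.zeros(M, dtype=np.bool_)
    order[0] = k0
    taken[k0] = True
    length = 1
    for _ in range(H - 1):
        last = order[length - 1]
        x = R[:, last].copy()
        nrm2 = 0.0
        for i in range(N):
            nrm2 += x[i] * x[i]
        if nrm2 < tol * tol:
            break
        # project all remaining columns out of x
        best = -1
        best_norm = 0.0
        for j in range(M):
            if taken[j]:
                continue
            dot = 0.0
            for i in range(N):
                dot += x[i] * R[i, j]
            coef = dot / nrm2
            cn = 0.0
            for i in range(N):
                R[i, j] -= coef * x[i]
                cn += R[i, j] * R[i, j]
            if cn > best_norm:
                best_norm = cn
                best = j
        if best < 0 or best_norm < tol * tol:
            break
        order[length] = best
        taken[best] = True
        length += 1
    return order, length


@njit(cache=True)
def _pls1_fold_sse(Xtr, ytr, Xte, yte, t, max_lv, sse_row):
    """Accumulate test SSE for prefix width ``t`` at every LV count.

    ``sse_row`` has length ``max_lv``; entry a-1 receives the SSE using
    ``a`` latent variables (values carried forward past NIPALS collapse).
    """
    ntr = Xtr.shape[0]
    nte = Xte.shape[0]
    amax = min(t, max_lv, ntr - 1)

    E = np.empty((ntr, t))
    Et = np.empty((nte, t))
    for j in range(t):
        m = 0.0
        for i in range(ntr):
            m += Xtr[i, j]
        m /= ntr
        for i in range(ntr):
            E[i, j] = Xtr[i, j] - m
        for i in range(nte):
            Et[i, j] = Xte[i, j] - m
    ym = 0.0
    for i in range(ntr):
        ym += ytr[i]
    ym /= ntr
    f = np.empty(ntr)
    for i in range(ntr):
        f[i] = ytr[i] - ym
    pred = np.full(nte, ym)

    cur = 0.0
    for i in range(nte):
        d = pred[i] - yte[i]
        cur += d * d

    w = np.empty(t)
    p = np.empty(t)
    ts = np.empty(ntr)
    us = np.empty(nte)
    alive = True
    for a in range(max_lv):
        if alive and a < amax:
            nw = 0.0
            for j in range(t):
                s = 0.0
                for i in range(ntr):
                    s += E[i, j] * f[i]
                w[j] = s
                nw += s * s
            nw = np.sqrt(nw)
            if nw < 1e-12:
                alive = False
            else:
                for j in range(t):
                    w[j] /= nw
                tt = 0.0
                for i in range(ntr):
                    s = 0.0
                    for j in range(t):
                        s += E[i, j] * w[j]
                    ts[i] = s
                    tt += s * s
                if tt < 1e-24:
                    alive = False
                else:
                    qa = 0.0
                    for i in range(ntr):
                        qa += ts[i] * f[i]
                    qa /= tt
                    for j in range(t):
                        s = 0.0
                        for i in range(ntr):
                            s += ts[i] * E[i, j]
                        p[j] = s / tt
                    for i in range(ntr):
                        for j in range(t):
                            E[i, j] -= ts[i] * p[j]
                        f[i] -= qa * ts[i]
                    for i in range(nte):
                        s = 0.0
                        for j in range(t):
                            s += Et[i, j] * w[j]
                        us[i] = s
                        pred[i] += qa * s
                        for j in range(t):
                            Et[i, j] -= s * p[j]
                    cur = 0.0
                    for i in range(nte):
                        d = pred[i] - yte[i]
                        cur += d * d
        sse_row[a] += cur


@njit(cache=True)
def pls1_prefix_sse(Xo, y, fold_id, n_folds, max_lv):
    """Cross-validated SSE for every column prefix of ``Xo`` at every LV.

    ``Xo`` holds the candidate variables in selection order.  Returns an
    (H, max_lv) array of pooled out-of-fold squared-error sums.
    """
    N, H = Xo.shape
    sse = np.zeros((H, max_lv))
    for fold in range(n_folds):
        ntr = 0
        for i in range(N):
            if fold_id[i] != fold:
                ntr += 1
        nte = N - ntr
        if nte == 0 or ntr < 2:
            continue
        Xtr = np.empty((ntr, H))
        ytr = np.empty(ntr)
        Xte = np.empty((nte, H))
        yte = np.empty(nte)
        ia = 0
        ib = 0
        for i in range(N):
            if fold_id[i] == fold:
                for j in range(H):
                    Xte[ib, j] = Xo[i, j]
                yte[ib] = y[i]
                ib += 1
            else:
                for j in range(H):
                    Xtr[ia, j] = Xo[i, j]
                ytr[ia] = y[i]
                ia += 1
        for t in range(1, H + 1):
            _pls1_fold_sse(Xtr[:, :t], ytr, Xte, yte, t, max_lv, sse[t - 1])
    return sse


@njit(cache=True)
def pls1_cv_sse(X, y, fold_id, n_folds, max_lv):
    """Cross-validated SSE of PLS1 on the full variable set at every LV."""
    N, p = X.shape
    sse = np.zeros((1, max_lv))
    for fold in range(n_folds):
        ntr = 0
        for i in range(N):
            if fold_id[i] != fold:
                ntr += 1
        nte = N - ntr
        if nte == 0 or ntr < 2:
            continue
        Xtr = np.empty((ntr, p))
        ytr = np.empty(ntr)
        Xte = np.empty((nte, p))
        yte = np.empty(nte)
        ia = 0
        ib = 0
        for i in range(N):
            if fold_id[i] == fold:
                for j in range(p):
                    Xte[ib, j] = X[i, j]
                yte[ib] = y[i]
                ib += 1
            else:
                for j in range(p):
                    Xtr[ia, j] = X[i, j]
                ytr[ia] = y[i]
                ia += 1
        _pls1_fold_sse(Xtr, ytr, Xte, yte, p, max_lv, sse[0])
    return sse[0]
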