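"""Desk-scale benchmark scenarios on synthetic data.

These scenarios exercise the full method end to end at sizes a laptop
handles in minutes, and quantify the two claims that matter for a variable
selector: does it find the channels that are truly informative (the
generator knows), and does the reduced model predict at least as well as
the full spectrum?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .ebspa import ebspa_select, run_bspa
from .preprocess import snv
from .spa import spa_select
from .split import spxy_split
from .synthetic import benchmark_config, simulate

__all__ = ["RecoveryResult", "recovery_benchmark", "sample_size_scenario"]


@dataclass
class RecoveryResult:
    """Per-seed outcomes of the selection-recovery benchmark."""

    seeds: list[int]
    n_selected: np.ndarray
    n_union: np.ndarray
    recovery: np.ndarray  # fraction of F_EB inside the truth mask, per seed
    rmsep_ebspa: np.ndarray
    rmsep_full: np.ndarray

    @property
    def pooled_recovery(self) -> float:
        """Truth-mask fraction pooled over all selected channels."""
        return float(np.sum(self.n_selected * self.recovery) / np.sum(self.n_selected))


def _eval_pls(X_cal, y_cal, X_val, y_val, cols, seed):
    model = models.fit_model(models.ModelSpec(kind="pls"), X_cal[:, cols], y_cal, seed=seed)
    return models.rmse(model.predict(X_val[:, cols]), y_val)


def recovery_benchmark(
    seeds=range(10), T: int = 10, H: int = 20, folds: int | str = 10
) -> RecoveryResult:
    """EBSPA-PLS vs full-spectrum PLS over seeded synthetic datasets.

    For each seed: simulate the reduced-grid dataset, SNV-correct, SPXY 2:1
    split, EBSPA on the calibration set (full k0 scan), then validation
    RMSEP of a PLS model on the selected channels and on the full spectrum.

    SNV is the pipeline default; note that it blurs the notion of an
    "uninformative" channel — dividing each spectrum by its own standard
    deviation, which itself tracks the analyte level, leaks concentration
    information into every channel (closure), so truth-mask recovery is a
    conservative lower bound on selector accuracy (see the methods note).
    """
    seeds = list(seeds)
    n_sel, n_uni, rec, r_eb, r_full = [], [], [], [], []
    for seed in seeds:
        ds = simulate(benchmark_config(seed=seed))
        Xs = snv(ds.X)
        sp = spxy_split(Xs, ds.y, 2.0)
        Xc, yc = Xs[sp.calibration_indices], ds.y[sp.calibration_indices]
        Xv, yv = Xs[sp.validation_indices], ds.y[sp.validation_indices]
        res = ebspa_select(Xc, yc, T=T, H=H, folds=folds, seed=seed)
        n_sel.append(res.n_selected)
        n_uni.append(res.union.size)
        rec.append(float(ds.truth_mask[res.final_selected].mean()))
        r_eb.append(_eval_pls(Xc, yc, Xv, yv, res.final_selected, seed))
        r_full.append(_eval_pls(Xc, yc, Xv, yv, np.arange(Xc.shape[1]), seed))
    return RecoveryResult(
        seeds=seeds,
        n_selected=np.array(n_sel),
        n_union=np.array(n_uni),
        recovery=np.array(rec),
        rmsep_ebspa=np.array(r_eb),
        rmsep_full=np.array(r_full),
    )


def sample_size_scenario(
    sizes=((27, 14), (54, 27), (81, 41), (108, 54)),
    T: int = 10,
    H: int = 20,
    seed: int = 0,
    k0_subsample: int | None = None,
    folds: int | str = 10,
) -> dict:
    """SPA vs bootstrap-ensemble SPA at shrinking sample sizes.

    Nested SPXY subsets of one synthetic dataset provide
    (calibration, validation) pairs of the given sizes; for each pair both
    the single SPA selection and the BSPA union are scored by validation
    RMSEP of a PLS model.  Illustrates the instability of single-run SPA on
    small calibration sets.
    """
    ds = simulate(benchmark_config(seed=seed))
    Xs = snv(ds.X)
    sp = spxy_split(Xs, ds.y, 2.0)
    k0 = None
    if k0_subsample is not None:
        k0 = np.unique(
            np.linspace(0, Xs.shape[1] - 1, k0_subsample).round().astype(int)
        )
    out = {}
    for n_cal, n_val in sizes:
        # representative subset of each split, SPXY within the split
        cal_pool = sp.calibration_indices
        val_pool = sp.validation_indices
        cal = cal_pool[_spxy_head(Xs[cal_pool], ds.y[cal_pool], n_cal)]
        val = val_pool[_spxy_head(Xs[val_pool], ds.y[val_pool], n_val)]
        Xc, yc, Xv, yv = Xs[cal], ds.y[cal], Xs[val], ds.y[val]
        chain = spa_select(Xc, yc, H=H, folds=folds, seed=seed, k0_candidates=k0)
        _, union = run_bspa(Xc, yc, T=T, H=H, folds=folds, seed=seed, k0_candidates=k0)
        out[(n_cal, n_val)] = {
            "spa_n": int(chain.h),
            "spa_rmsep": _eval_pls(Xc, yc, Xv, yv, chain.selected, seed),
            "bspa_n": int(union.size),
            "bspa_rmsep": _eval_pls(Xc, yc, Xv, yv, union, seed),
        }
    return out


def _spxy_head(X, y, n_keep):
    """Indices of the n_keep most representative samples (SPXY order)."""
    if n_keep >= X.shape[0]:
        return np.arange(X.shape[0])
    sub = spxy_split(X, y, ratio=n_keep / (X.shape[0] - n_keep))
    return sub.calibration_indices
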