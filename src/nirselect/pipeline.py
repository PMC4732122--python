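"""End-to-end calibration pipeline: preprocess -> split -> select -> fit -> evaluate.

``RunConfig`` is the single serialisable source of truth for a run; every
random draw in the pipeline derives from ``config.seed``, so a given
(config, dataset) pair always produces an identical report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import baselines, ebspa, models, preprocess, spa, split as split_mod
from .synthetic import SpectralDataset

__all__ = ["RunConfig", "EvaluationReport", "run_pipeline", "run_selector"]

log = logging.getLogger("nirselect")

SELECTORS = ("spa", "bspa", "ebspa", "fipls", "bipls", "uve", "mcuve", "cars", "none")
MODELS = ("mlr", "pls", "lssvm")


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run (flat, serialisable).

    ``H`` is the maximum chain length of the projection search, ``T`` the
    number of bootstrap iterations of the ensemble, ``cv_folds`` the fold
    count (or ``"loo"``) used everywhere a cross-validated error appears.
    ``k0_subsample`` optionally limits the number of scanned start channels
    (evenly spaced) for large spectra; ``None`` scans all channels.
    """

    preprocess_method: str = "snv"
    split_ratio: float = 2.0
    selector: str = "ebspa"
    model: str = "pls"
    H: int = 20
    T: int = 10
    cv_folds: int | str = 10
    seed: int = 0
    max_lv: int = models.DEFAULT_MAX_LV
    n_intervals: int = 30
    uve_threshold: float = 0.9
    cars_runs: int = 500
    mcuve_runs: int = 10
    mcuve_eval_step: int = 10
    k0_subsample: int | None = None
    alpha_scheme: str = "h"

    def __post_init__(self) -> None:
        if self.preprocess_method not in preprocess.METHODS:
            raise ValueError(f"unknown preprocess method {self.preprocess_method!r}")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.H < 1 or self.T < 1 or self.split_ratio <= 0:
            raise ValueError("require H >= 1, T >= 1, split_ratio > 0")
        if self.cv_folds != "loo" and int(self.cv_folds) < 2:
            raise ValueError("cv_folds must be >= 2 or 'loo'")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EvaluationReport:
    """Calibration/validation figures of merit for one fitted model.

    R1/RMSEC describe the calibration fit, RMSECV the cross-validated
    error on the calibration set, and R2/RMSEP the validation
    (prediction) performance.
    """

    R_calibration: float
    R_validation: float
    RMSEC: float
    RMSECV: float
    RMSEP: float
    n_selected: int
    selected_wavenumbers: list[float]
    selector: str
    model: str
    preprocess_method: str
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_selected != len(self.selected_wavenumbers):
            raise ValueError("n_selected must equal len(selected_wavenumbers)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _k0_candidates(m: int, subsample: int | None) -> np.ndarray | None:
    if subsample is None or subsample >= m:
        return None
    return np.unique(np.linspace(0, m - 1, subsample).round().astype(int))


def run_selector(
    config: RunConfig, X_cal: np.ndarray, y_cal: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Run the configured selector on the calibration set.

    Returns (sorted channel indices, extras dict with selector detail).
    """
    sel = config.selector
    spec = models.ModelSpec(kind="pls", max_lv=config.max_lv)
    folds, seed = config.cv_folds, config.seed
    extras: dict = {}
    if sel == "none":
        return np.arange(X_cal.shape[1]), extras
    if sel == "spa":
        chain = spa.spa_select(
            X_cal, y_cal, H=config.H, model_spec=spec, folds=folds, seed=seed,
            k0_candidates=_k0_candidates(X_cal.shape[1], config.k0_subsample),
        )
        extras = {
            "k0": int(chain.k0),
            "order": chain.order.tolist(),
            "rmsecv_by_length": chain.rmsecv_by_length.tolist(),
            "h": int(chain.h),
        }
        return np.sort(chain.selected), extras
    if sel == "bspa":
        chains, union = ebspa.run_bspa(
            X_cal, y_cal, T=config.T, H=config.H, model_spec=spec, folds=folds,
            seed=seed, k0_candidates=_k0_candidates(X_cal.shape[1], config.k0_subsample),
        )
        extras = {"chain_sizes": [int(c.h) for c in chains], "union_size": int(union.size)}
        return union, extras
    if sel == "ebspa":
        result = ebspa.ebspa_select(
            X_cal, y_cal, T=config.T, H=config.H, model_spec=spec, folds=folds,
            seed=seed, k0_candidates=_k0_candidates(X_cal.shape[1], config.k0_subsample),
            alpha_scheme=config.alpha_scheme,
        )
        extras = {
            "union_size": int(result.union.size),
            "accumulation_rmsecv": result.accumulation_rmsecv.tolist(),
            "sorted_order": result.sorted_order.tolist(),
            "ensemble": result,
        }
        return np.sort(result.final_selected), extras
    if sel == "fipls":
        return baselines.fipls(X_cal, y_cal, config.n_intervals, folds, seed, config.max_lv), extras
    if sel == "bipls":
        return baselines.bipls(X_cal, y_cal, config.n_intervals, folds, seed, config.max_lv), extras
    if sel == "uve":
        return baselines.uve(X_cal, y_cal, config.uve_threshold, folds, seed, config.max_lv), extras
    if sel == "mcuve":
        return baselines.mc_uve(
            X_cal, y_cal, config.mcuve_runs, config.mcuve_eval_step, folds, seed,
            max_lv=config.max_lv,
        ), extras
    if sel == "cars":
        return baselines.cars(
            X_cal, y_cal, config.cars_runs, 5, seed, max_lv=config.max_lv
        ), extras
    raise ValueError(f"unknown selector {sel!r}")


def run_pipeline(config: RunConfig, dataset: SpectralDataset) -> EvaluationReport:
    """Execute the full pipeline on a dataset and evaluate the final model.

    Order of operations: preprocessing is applied to all spectra (it is
    per-spectrum and split-independent), the SPXY split is computed on the
    preprocessed spectra, selection and model fitting use the calibration
    split only, and the validation split is touched once at the end.  MSC
    is the exception: its reference must be the calibration mean, so the
    split is computed on the raw spectra first and the reference then
    frozen from the calibration split.
    """
    wn = dataset.wavenumbers
    if config.preprocess_method == "msc":
        sp = split_mod.spxy_split(dataset.X, dataset.y, config.split_ratio)
        reference = dataset.X[sp.calibration_indices].mean(axis=0)
        state = preprocess.PreprocessState(method="msc", reference_spectrum=reference)
        X_all = preprocess.apply_method(dataset.X, state, wn)
    else:
        state = preprocess.PreprocessState(method=config.preprocess_method)
        X_all = preprocess.apply_method(dataset.X, state, wn)
        sp = split_mod.spxy_split(X_all, dataset.y, config.split_ratio)

    cal, val = sp.calibration_indices, sp.validation_indices
    X_cal, y_cal = X_all[cal], dataset.y[cal]
    X_val, y_val = X_all[val], dataset.y[val]
    log.info("split: %d calibration / %d validation samples", cal.size, val.size)

    selected, extras = run_selector(config, X_cal, y_cal)
    log.info("selector %s kept %d of %d channels", config.selector,
             selected.size, X_cal.shape[1])
    ensemble = extras.pop("ensemble", None)

    spec = models.ModelSpec(kind=config.model, max_lv=config.max_lv)
    fitted = models.fit_model(spec, X_cal[:, selected], y_cal,
                              folds=config.cv_folds, seed=config.seed)
    if fitted.kind == "pls":
        spec = dataclasses.replace(spec, n_latent=fitted.n_components_)
        extras["n_latent"] = int(fitted.n_components_)
    elif fitted.kind == "lssvm":
        spec = dataclasses.replace(spec, gamma=fitted.gamma, sigma2=fitted.sigma2)
        extras["gamma"] = fitted.gamma
        extras["sigma2"] = fitted.sigma2

    pred_cal = fitted.predict(X_cal[:, selected])
    pred_val = fitted.predict(X_val[:, selected])
    cv = models.cross_validate(spec, X_cal[:, selected], y_cal,
                               folds=config.cv_folds, seed=config.seed)
    report = EvaluationReport(
        R_calibration=models.pearson_r(pred_cal, y_cal),
        R_validation=models.pearson_r(pred_val, y_val),
        RMSEC=models.rmse(pred_cal, y_cal),
        RMSECV=cv.best_rmsecv,
        RMSEP=models.rmse(pred_val, y_val),
        n_selected=int(selected.size),
        selected_wavenumbers=[float(wn[i]) for i in selected],
        selector=config.selector,
        model=config.model,
        preprocess_method=config.preprocess_method,
        seed=config.seed,
        extras=extras,
    )
    log.info("RMSEC=%.4g RMSECV=%.4g RMSEP=%.4g", report.RMSEC, report.RMSECV,
             report.RMSEP)
    if ensemble is not None:
        report.extras["ei"] = {
            "variables": ensemble.ei.variables.tolist(),
            "alpha": ensemble.ei.alpha.tolist(),
            "p": ensemble.ei.purity.tolist(),
            "b": ensemble.ei.b.tolist(),
            "w": ensemble.ei.w.tolist(),
        }
    return report
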