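"""Spectral preprocessing transforms.

The standard NIR screening menu: raw, multiplicative scatter correction
(MSC), standard normal variate (SNV), SNV + detrend, Savitzky-Golay
smoothing, sliding-window (moving average) smoothing, and first/second
Savitzky-Golay derivatives.

All transforms operate row-wise (per spectrum) and preserve the matrix
shape.  The single exception to split-independence is MSC, whose reference
spectrum must be learned on the calibration split and applied frozen to
validation spectra.  Standard deviations use the sample (n-1) convention
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessState",
    "METHODS",
    "snv",
    "msc",
    "detrend",
    "snv_detrend",
    "sg_smooth",
    "sw_smooth",
    "derivative",
    "apply_method",
]

#: Method tags accepted by :func:`apply_method`.
METHODS = ("raw", "msc", "snv", "snv_dt", "sg", "sw", "der1", "der2")


@dataclass
class PreprocessState:
    """Frozen preprocessing parameters for one run.

    ``reference_spectrum`` is only set for MSC and must be the mean
    calibration spectrum.
    """

    method: str = "snv"
    reference_spectrum: np.ndarray | None = None
    sg_window: int = 11
    sg_polyorder: int = 2
    sw_window: int = 11
    derivative_gap: int = 11  # SG window used for derivative filters

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        for w in (self.sg_window, self.sw_window, self.derivative_gap):
            if w < 3 or w % 2 == 0:
                raise ValueError(f"window sizes must be odd and >= 3, got {w}")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("polyorder must be < window")


def _as_matrix(spectra: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centre and scale to unit sd.

    Rejects flat (zero-variance) spectra, which carry no information.
    """
    X, squeeze = _as_matrix(spectra)
    if X.shape[1] < 2:
        raise ValueError("SNV needs >= 2 channels")
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance spectrum at row {bad}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if squeeze else out


def msc(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a fixed reference.

    Each spectrum is regressed on the reference (OLS with intercept) and the
    fitted affine distortion is inverted: ``(x - intercept) / slope``.
    """
    X, squeeze = _as_matrix(spectra)
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or ref.shape[0] != X.shape[1]:
        raise ValueError("reference length must equal channel count")
    if X.shape[1] < 2:
        raise ValueError("MSC needs >= 2 channels")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate (constant) MSC reference")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    slope = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(slope == 0):
        raise ValueError("spectrum orthogonal to reference; MSC slope is zero")
    intercept = X.mean(axis=1) - slope * ref.mean()
    out = (X - intercept[:, None]) / slope[:, None]
    return out[0] if squeeze else out


def detrend(spectra: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Subtract each spectrum's least-squares line against wavenumber."""
    X, squeeze = _as_matrix(spectra)
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.shape[0] != X.shape[1]:
        raise ValueError("wavenumber length must equal channel count")
    wc = wn - wn.mean()
    denom = wc @ wc
    slope = X @ wc / denom
    out = X - X.mean(axis=1, keepdims=True) - np.outer(slope, wc)
    return out[0] if squeeze else out


def snv_detrend(spectra: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """SNV followed by detrending (SNV + DT)."""
    return detrend(snv(spectra), wavenumbers)


def sg_smooth(spectra: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing; edges handled by boundary polynomial fits."""
    X, squeeze = _as_matrix(spectra)
    out = savgol_filter(X, window, polyorder, axis=1, mode="interp")
    return out[0] if squeeze else out


def sw_smooth(spectra: np.ndarray, window: int = 11) -> np.ndarray:
    """Sliding-window (moving-average) smoothing."""
    X, squeeze = _as_matrix(spectra)
    out = uniform_filter1d(X, size=window, axis=1, mode="nearest")
    return out[0] if squeeze else out


def derivative(
    spectra: np.ndarray, order: int = 1, window: int = 11, polyorder: int = 2
) -> np.ndarray:
    """Savitzky-Golay derivative of order 1 or 2, per channel index.

    The derivative is taken with respect to channel position (unit spacing),
    so a linear ramp maps to a constant equal to its per-channel slope.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    X, squeeze = _as_matrix(spectra)
    out = savgol_filter(X, window, max(polyorder, order), deriv=order, axis=1, mode="interp")
    return out[0] if squeeze else out


def apply_method(
    spectra: np.ndarray, state: PreprocessState, wavenumbers: np.ndarray | None = None
) -> np.ndarray:
    """Dispatch one of the eight transforms according to ``state.method``."""
    m = state.method
    if m == "raw":
        return np.asarray(spectra, dtype=float).copy()
    if m == "snv":
        return snv(spectra)
    if m == "msc":
        if state.reference_spectrum is None:
            raise ValueError("MSC requires a reference spectrum (calibration mean)")
        return msc(spectra, state.reference_spectrum)
    if m == "snv_dt":
        if wavenumbers is None:
            raise ValueError("snv_dt requires wavenumbers")
        return snv_detrend(spectra, wavenumbers)
    if m == "sg":
        return sg_smooth(spectra, state.sg_window, state.sg_polyorder)
    if m == "sw":
        return sw_smooth(spectra, state.sw_window)
    if m in ("der1", "der2"):
        return derivative(spectra, 1 if m == "der1" else 2, state.derivative_gap,
                          state.sg_polyorder)
    raise ValueError(f"unknown preprocessing method {m!r}")
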