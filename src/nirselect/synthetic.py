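"""Synthetic two-component NIR mixture spectra.

Emulates absorbance spectra of binary liquid mixtures (an ethanol/water-like
system) on a wavenumber grid, under Beer–Lambert additivity: each pure
component contributes a sum of Gaussian absorption bands, and a mixture at
analyte fraction ``c`` absorbs ``c*A_analyte + (1-c)*A_matrix``.  On top of
the ideal mixture the generator adds the three nuisances that dominate real
NIR measurements: a per-spectrum multiplicative scatter factor, a per-spectrum
linear baseline drift, and i.i.d. channel noise.

Because the generator knows which channels belong to analyte bands, every
dataset carries a ``truth_mask`` so that variable-selection accuracy can be
scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BandSpec",
    "SimulationConfig",
    "SpectralDataset",
    "make_grid",
    "simulate",
    "default_config",
    "benchmark_config",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band of a pure component.

    Parameters
    ----------
    center : float
        Band center (cm^-1).  Must lie inside the wavenumber grid.
    width : float
        Gaussian standard deviation (cm^-1), > 0.
    amplitude : float
        Peak absorbance (AU), >= 0.
    component : str
        ``"analyte"`` or ``"matrix"``.
    """

    center: float
    width: float
    amplitude: float
    component: str = "analyte"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.component not in ("analyte", "matrix"):
            raise ValueError(f"component must be 'analyte' or 'matrix', got {self.component!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid."""
        return self.amplitude * np.exp(-0.5 * ((wavenumbers - self.center) / self.width) ** 2)


def _default_bands() -> tuple[BandSpec, ...]:
    # Analyte combination bands near 5162 and 4400 cm^-1 (the 5162 cm^-1 peak
    # is the classic O-H/C-H combination feature used for alcohol assays);
    # broad water-like matrix bands near 5200 and 6900 cm^-1.
    return (
        BandSpec(5162.0, 60.0, 1.0, "analyte"),
        BandSpec(4400.0, 90.0, 0.5, "analyte"),
        BandSpec(5200.0, 45.0, 0.5, "matrix"),
        BandSpec(6900.0, 110.0, 0.8, "matrix"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic acquisition.

    Defaults mirror a bench FT-NIR setup: 12,000 -> 4,000 cm^-1 at 2 cm^-1
    spacing (4001 channels) and an analyte-fraction ladder 0.045 -> 0.850 in
    steps of 0.005 (162 samples).
    """

    wn_start: float = 12000.0
    wn_end: float = 4000.0
    wn_step: float = 2.0
    conc_start: float = 0.045
    conc_end: float = 0.850
    conc_step: float = 0.005
    bands: tuple[BandSpec, ...] = field(default_factory=_default_bands)
    scatter_sd: float = 0.02
    baseline_sd: float = 0.01
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_sd", "baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SpectralDataset:
    """Absorbance matrix with wavenumber grid and reference concentrations.

    Attributes
    ----------
    X : ndarray, shape (N, M)
        Absorbance (AU), N samples by M channels.
    wavenumbers : ndarray, shape (M,)
        Channel positions (cm^-1), strictly monotone.
    y : ndarray, shape (N,)
        Analyte concentration as a fraction in [0, 1].
    truth_mask : ndarray of bool, shape (M,), optional
        Channels lying inside analyte bands (synthetic data only).
    """

    X: np.ndarray
    wavenumbers: np.ndarray
    y: np.ndarray
    truth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x channels)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"row count of X ({self.X.shape[0]}) != length of y ({self.y.shape[0]})"
            )
        if self.X.shape[1] != self.wavenumbers.shape[0]:
            raise ValueError(
                f"column count of X ({self.X.shape[1]}) != number of wavenumbers "
                f"({self.wavenumbers.shape[0]})"
            )
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("dataset contains non-finite entries")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
            if self.truth_mask.shape != self.wavenumbers.shape:
                raise ValueError("truth_mask length must equal channel count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        """Dataset restricted to the given sample indices."""
        return SpectralDataset(
            self.X[rows], self.wavenumbers, self.y[rows], truth_mask=self.truth_mask
        )


def make_grid(start: float, end: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid from ``start`` to ``end`` with spacing ``step``.

    ``step`` is an unsigned spacing; the direction is taken from the sign of
    ``end - start``, so ``make_grid(12000, 4000, 2)`` yields a descending grid.

    Raises
    ------
    ValueError
        If the span is not an integer multiple of the step (misconfiguration
        rather than silent truncation).
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    span = end - start
    if span == 0:
        raise ValueError("start and end must differ")
    n = abs(span) / step
    n_round = round(n)
    if n_round == 0 or abs(n - n_round) > 1e-8 * max(1.0, n):
        raise ValueError(
            f"span |{end} - {start}| = {abs(span)} is not an integer multiple of step {step}"
        )
    return np.linspace(start, end, n_round + 1)


def component_profile(
    bands: tuple[BandSpec, ...] | list[BandSpec], wavenumbers: np.ndarray, component: str
) -> np.ndarray:
    """Sum of one component's Gaussian bands on a grid."""
    out = np.zeros_like(wavenumbers, dtype=float)
    for band in bands:
        if band.component == component:
            out += band.profile(wavenumbers)
    return out


def simulate(config: SimulationConfig) -> SpectralDataset:
    """Generate a :class:`SpectralDataset` from a :class:`SimulationConfig`.

    For each concentration ``c`` on the grid the spectrum is

        m * (c * A_analyte + (1 - c) * A_matrix) + b0 + b1 * u + noise

    with ``m ~ N(1, scatter_sd)``, ``b0, b1 ~ N(0, baseline_sd)``, ``u`` the
    wavenumber normalised to [0, 1], and channel noise ``N(0, noise_sd)``.
    Fully reproducible from ``config.seed``.
    """
    wn = make_grid(config.wn_start, config.wn_end, config.wn_step)
    y = make_grid(config.conc_start, config.conc_end, config.conc_step)
    if wn.size < 2 or y.size < 2:
        raise ValueError("grids must produce >= 2 channels and >= 2 samples")

    lo, hi = min(wn[0], wn[-1]), max(wn[0], wn[-1])
    for band in config.bands:
        if not (lo <= band.center <= hi):
            raise ValueError(
                f"band center {band.center} cm^-1 lies outside the grid [{lo}, {hi}]"
            )

    a_analyte = component_profile(config.bands, wn, "analyte")
    a_matrix = component_profile(config.bands, wn, "matrix")

    n, m = y.size, wn.size
    rng = np.random.default_rng(config.seed)
    scatter = rng.normal(1.0, config.scatter_sd, size=n)
    b0 = rng.normal(0.0, config.baseline_sd, size=n)
    b1 = rng.normal(0.0, config.baseline_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, m))

    u = (wn - lo) / (hi - lo)
    ideal = np.outer(y, a_analyte) + np.outer(1.0 - y, a_matrix)
    X = scatter[:, None] * ideal + b0[:, None] + np.outer(b1, u) + noise

    truth = np.zeros(m, dtype=bool)
    for band in config.bands:
        if band.component == "analyte":
            truth |= np.abs(wn - band.center) <= 2.0 * band.width
    return SpectralDataset(X, wn, y, truth_mask=truth)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The full-grid default acquisition (4001 channels, 162 samples)."""
    return replace(SimulationConfig(seed=seed), **overrides)


def benchmark_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced desk-scale acquisition used by the selection benchmarks.

    Restricts the grid to the 6000 -> 4000 cm^-1 combination-band region
    (501 channels at 4 cm^-1) that contains the analyte bands, dropping the
    6900 cm^-1 matrix band that falls outside the window.  Concentration grid
    and noise levels are unchanged from the default.
    """
    bands = tuple(b for b in _default_bands() if 4000.0 <= b.center <= 6000.0)
    cfg = SimulationConfig(
        wn_start=6000.0, wn_end=4000.0, wn_step=4.0, bands=bands, seed=seed
    )
    return replace(cfg, **overrides)
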