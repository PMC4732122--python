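"""Shared fixtures: small synthetic datasets that keep tests desk-scale."""

import numpy as np
import pytest
from hypothesis import settings

from nirselect.synthetic import BandSpec, SimulationConfig, simulate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def tiny_config(seed: int = 0, **overrides) -> SimulationConfig:
    """41 channels (5400 -> 4900 cm^-1), 29 samples; one analyte and one
    matrix band.  Small enough for exhaustive oracles."""
    defaults = dict(
        wn_start=5400.0,
        wn_end=4900.0,
        wn_step=12.5,
        conc_start=0.1,
        conc_end=0.8,
        conc_step=0.025,
        bands=(
            BandSpec(5162.0, 60.0, 1.0, "analyte"),
            BandSpec(5200.0, 45.0, 0.5, "matrix"),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def tiny_dataset():
    return simulate(tiny_config())


@pytest.fixture
def noise_free_dataset():
    return simulate(tiny_config(scatter_sd=0.0, baseline_sd=0.0, noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
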