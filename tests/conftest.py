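import numpy as np
import pytest

from azmech.synthetic import (
    GeneratorConfig,
    apo_pathways,
    gaussian_irf,
    generate_dataset,
    generate_toy_barrel,
)


@pytest.fixture(scope="session")
def barrel():
    """8-strand toy barrel with the 5-ligand copper site."""
    return generate_toy_barrel(8, 6, with_metal_site=True, seed=0)


@pytest.fixture(scope="session")
def small_barrel():
    """Cheap 6-strand barrel for fast simulator unit tests."""
    return generate_toy_barrel(6, 4, with_metal_site=False, seed=0)


@pytest.fixture(scope="session")
def apo_traces():
    """30 noisy heptamer traces from the apo mixture (fixed seeds)."""
    cfg = GeneratorConfig(seed=0, noise_sd=5.0)
    return generate_dataset(cfg, apo_pathways(), 30, seed=123)


@pytest.fixture(scope="session")
def apo_traces_100():
    """Larger noisy ensemble for statistical recovery checks."""
    cfg = GeneratorConfig(seed=0, noise_sd=5.0)
    return generate_dataset(cfg, apo_pathways(), 100, seed=123)


@pytest.fixture(scope="session")
def noiseless_trace():
    cfg = GeneratorConfig(seed=0, noise_sd=0.0)
    from azmech.synthetic import generate_fx_trace

    return generate_fx_trace(cfg, apo_pathways())


@pytest.fixture(scope="session")
def irf80():
    """Realistic 80 ps FWHM instrument response on the 48.9 ps grid."""
    return gaussian_irf(n_channels=1024, channel_width=48.9, fwhm=80.0, t0=500.0)
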