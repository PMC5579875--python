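import numpy as np
import pytest

from hsigrade import SyntheticConfig, make_wavelength_axis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def axis256():
    """The default 256-band instrument axis (200 bands in 975.01-1645.82)."""
    return make_wavelength_axis(256, 975.01, 1645.82, 200)


@pytest.fixture(scope="session")
def default_table():
    """Spectrum table of the full default synthetic dataset (built once)."""
    from hsigrade.pipeline import build_spectrum_table

    return build_spectrum_table(SyntheticConfig()).subset_bands(975.01, 1645.82)


@pytest.fixture
def tiny_config():
    """Small images / few samples: fast, same spectral regime as defaults."""
    return SyntheticConfig(n_intact_per_grade=3, slices_per_sausage=2, rows=24, cols=16)


@pytest.fixture
def clean_config():
    """Deterministic composition: no fraction dispersion, scatter or noise."""
    return SyntheticConfig(
        n_intact_per_grade=2, slices_per_sausage=1, rows=24, cols=16,
        fraction_concentration=np.inf, pixel_concentration=np.inf,
        scatter_sd=0.0, noise_sd=0.0,
    )
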