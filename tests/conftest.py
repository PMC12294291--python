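import numpy as np
import pytest

from copigmentation.spectra import SampleMeta, Spectrum


@pytest.fixture
def grid():
    return np.arange(300.0, 701.0, 1.0)


@pytest.fixture
def gaussian_spectrum(grid):
    """Flavylium-like band: Gaussian centred at 523 nm, peak 0.5 AU."""

    def make(centre=523.0, width=40.0, amplitude=0.5, meta=None):
        ab = amplitude * np.exp(-0.5 * ((grid - centre) / width) ** 2)
        return Spectrum(grid, ab, meta or SampleMeta())

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
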