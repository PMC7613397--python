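import numpy as np
import pytest

from specal import (
    TraitRanges, default_wavelengths, sample_traits, surrogate_forward,
)
from specal.dimred import fit_pca


@pytest.fixture(scope="session")
def ranges():
    return TraitRanges()


@pytest.fixture(scope="session")
def wavelengths():
    return default_wavelengths()


@pytest.fixture(scope="session")
def lut200(ranges, wavelengths):
    """Small noise-free surrogate LUT shared across tests."""
    traits = sample_traits(ranges, 200, seed=3)
    spectra = surrogate_forward(traits, wavelengths)
    return traits, spectra


@pytest.fixture(scope="session")
def features200(lut200):
    """PCA features (12 components) of the shared LUT."""
    traits, spectra = lut200
    pca = fit_pca(spectra, 12)
    return pca, pca.transform(spectra), traits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
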