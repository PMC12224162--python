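import numpy as np
import pytest

from hilicraman import presets
from hilicraman.core import TimeAxis, WavenumberAxis
from hilicraman.decompose import ComponentLibrary, svd_factor, target_rotation


@pytest.fixture(scope="session")
def waxis():
    return presets.default_wavenumber_axis()


@pytest.fixture(scope="session")
def taxis():
    return presets.default_time_axis()


@pytest.fixture(scope="session")
def spectra(waxis):
    return presets.model_spectra(waxis)


def full_library(spectra, analytes=presets.SUGARS):
    """Targets used throughout: analytes + ACN + water + band-shift + baseline."""
    targets = [spectra[s] for s in analytes] + [
        spectra["ACN"], spectra["H2O"], spectra["ACN-shift"], spectra["baseline"]
    ]
    return ComponentLibrary(targets)


@pytest.fixture(scope="session")
def noiseless_mixture():
    """Five sugars at 25 mM each, no noise, masked: a rank-9 bilinear model."""
    return presets.sugar_mixture_run(
        {s: 25.0 for s in presets.SUGARS}, seed=11, noise_sigma=0.0, masked=True
    )


@pytest.fixture(scope="session")
def noiseless_fru():
    """Single 200 mM fructose standard, no noise: six components incl. drift."""
    return presets.single_sugar_run("Fru", 200.0, seed=12, noise_sigma=0.0, masked=True)


@pytest.fixture(scope="session")
def mixture_decomposition(noiseless_mixture, spectra):
    chrom, truth = noiseless_mixture
    D = target_rotation(svd_factor(chrom), 9, full_library(spectra))
    return D, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
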