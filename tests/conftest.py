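import numpy as np
import pytest

from nirclass.io import SpectraSet
from nirclass.synthetic_data import SynthConfig, generate_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_set():
    """3 samples x 5 channels, hand-written values."""
    return SpectraSet(
        wavenumbers=np.array([4000.0, 4008.0, 4016.0, 4024.0, 4032.0]),
        absorbance=np.array([[0.1, 0.2, 0.3, 0.2, 0.1],
                             [0.2, 0.3, 0.4, 0.3, 0.2],
                             [0.15, 0.22, 0.35, 0.28, 0.12]]),
        labels=np.array(["a", "b", "a"]),
        sample_ids=np.array([1, 2, 3]),
    )


@pytest.fixture(scope="session")
def default_set():
    """One default synthetic draw (with injected outliers), shared
    read-only across tests."""
    return generate_spectra(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def clean_set():
    """A synthetic draw without injected outliers."""
    return generate_spectra(SynthConfig(seed=7, outliers=()))
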