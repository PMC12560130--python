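import numpy as np
import pytest

from plasmotaste.fingerprinting import SimulatedSource, run_session
from plasmotaste.synthetic_chip import (
    ResponseModel,
    default_catalog,
    default_chemistries,
    default_layout,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def chemistries():
    return default_chemistries(seed=0)


@pytest.fixture(scope="session")
def response_model():
    return ResponseModel()


@pytest.fixture(scope="session")
def noiseless_model():
    return ResponseModel(intensity_noise_sd=0.0)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog(seed=42)


@pytest.fixture(scope="session")
def session_matrix(catalog, chemistries):
    """The default full synthetic session: 1230 fingerprint rows."""
    source = SimulatedSource(chemistries=chemistries)
    return run_session(catalog, source=source, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
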