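import numpy as np
import pytest
from hypothesis import settings

from alkaquant import load_default_panel
from alkaquant.simulate import MatrixRecoveryModel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def small_panel(panel):
    """Three analytes spanning early, mid and late elution."""
    return panel.subset(["Ec", "At", "Lc"])


@pytest.fixture()
def unit_model():
    """Noise-free ideal instrument with unit response (areas == extract conc)."""
    return MatrixRecoveryModel(recovery=1.0, suppression=0.0,
                               response_factor=1.0, noise_sd=0.0,
                               baseline_level=0.0)


@pytest.fixture()
def clean_model():
    """Noise-free instrument at the default response scale."""
    return MatrixRecoveryModel(recovery=1.0, suppression=0.0,
                               response_factor=1.0e4, noise_sd=0.0,
                               baseline_level=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
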