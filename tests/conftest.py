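import pytest
from hypothesis import HealthCheck, settings

from thalabeta import ModelParameters, SimulationConfig, SpectralConfig, calibrate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Baseline model constants with the standard sensory drive."""
    return ModelParameters(mu_r=86.0)


@pytest.fixture(scope="session")
def mapping():
    """Amyloid transfer calibrated with the default clinical constants."""
    return calibrate()


@pytest.fixture(scope="session")
def short_config():
    """A brief schedule for integration-level tests."""
    return SimulationConfig(duration=8.0, dt=1e-3, transient=2.0, n_repeats=2, seed=0)


@pytest.fixture(scope="session")
def spectral_config():
    return SpectralConfig(fs=1000.0)
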