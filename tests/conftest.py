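import numpy as np
import pytest

from teamsync import SimulationConfig


@pytest.fixture
def quiet_config():
    """Short, noise-free, drift-free match: analytic kinematics apply."""
    return SimulationConfig(
        duration=300.0,
        noise_sd=0.0,
        drift_speed=0.0,
        gap_fraction=0.0,
        seed=7,
    )


@pytest.fixture
def short_config():
    """Short match with the default noise/drift/coupling conditions."""
    return SimulationConfig(duration=300.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
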