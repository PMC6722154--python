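import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from egopoint.session_model import RoomLayout, default_roster
from egopoint.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return RoomLayout()


@pytest.fixture(scope="session")
def roster(layout):
    return default_roster(layout)


@pytest.fixture(scope="session")
def small_cohort():
    """Five simulated participants, default study conditions."""
    config = SimConfig(n_participants=5, seed=7)
    sessions, truth = simulate_cohort(config)
    return config, sessions, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
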