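import warnings

import numpy as np
import pytest

from careact import SimulationConfig, build_schedule, generate_population

warnings.filterwarnings("ignore", message="fewer than 4 event types")


@pytest.fixture(scope="session")
def drop_config():
    return SimulationConfig(
        n_units=80,
        seed=9,
        sessions=(("drop", 1), ("drop", 2), ("drop", 3)),
    )


@pytest.fixture(scope="session")
def drop_session(drop_config):
    """A small parametric-drop experiment shared across tests."""
    schedule = build_schedule(drop_config)
    spikes, truth = generate_population(drop_config, schedule)
    return drop_config, schedule, spikes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
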