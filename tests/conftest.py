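import numpy as np
import pytest

from imupos.pipeline import simulated_feature_table
from imupos.synthetic import SimulationConfig, draw_subjects, simulate_recording


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale cohort: 3 subjects, short walk, accelerometer."""
    return SimulationConfig(n_subjects=3, walk_seconds=30.0, seed=11)


@pytest.fixture(scope="session")
def tiny_subjects(tiny_config):
    return draw_subjects(tiny_config)


@pytest.fixture(scope="session")
def tiny_recording(tiny_config, tiny_subjects):
    return simulate_recording(
        tiny_subjects[0], "right_thigh", "accelerometer", tiny_config
    )


@pytest.fixture(scope="session")
def tiny_features(tiny_config):
    """Accelerometer feature table of the tiny cohort (3 x 6 recordings)."""
    return simulated_feature_table(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
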