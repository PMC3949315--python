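import numpy as np
import pytest

from reachgen.kinematics import ArmModel
from reachgen.predictions import (
    TRAIN_POSTURE,
    build_test_movements,
    compute_predictions,
    distance_table,
)


@pytest.fixture(scope="session")
def arm():
    return ArmModel()


@pytest.fixture(scope="session")
def movements(arm):
    return build_test_movements(arm, TRAIN_POSTURE)


@pytest.fixture(scope="session")
def prediction_set(arm):
    """Normalized J/C/O predictions at the 15 test movements (computed once)."""
    return compute_predictions(arm=arm)


@pytest.fixture(scope="session")
def distances(arm):
    return distance_table(arm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
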