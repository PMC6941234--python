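import numpy as np
import pytest

from fourpath.core import PresynEventTrain, VoltageTrace
from fourpath.neuron import ActiveEventConfig, load_morphology
from fourpath.params import PlasticityParams, read_parameter_set


@pytest.fixture(scope="session")
def morph():
    return load_morphology("reduced_l5")


@pytest.fixture(scope="session")
def active_cfg():
    return ActiveEventConfig()


@pytest.fixture(scope="session")
def set1():
    return read_parameter_set("set1")


@pytest.fixture(scope="session")
def set2():
    return read_parameter_set("set2")


@pytest.fixture(scope="session")
def set3():
    return read_parameter_set("set3")


@pytest.fixture
def default_params():
    return PlasticityParams()


@pytest.fixture
def bump_trace():
    """Smooth suprathreshold voltage bump with two presynaptic events."""
    dt = 0.025
    t = np.arange(0, 200 + dt / 2, dt)
    u = -70 + 35 * np.exp(-((t - 80) / 12) ** 2) \
        + 55 * np.exp(-((t - 100) / 4) ** 2)
    return (VoltageTrace(0.0, dt, u),
            PresynEventTrain(np.array([75.0, 95.0])))
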