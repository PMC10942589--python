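import numpy as np
import pytest

from wlpkit.layout import ElectrodeLayout
from wlpkit.lfp import FilterSpec
from wlpkit.simulate import generate_recording, generate_trials, two_module_config


@pytest.fixture(scope="session")
def default_config():
    return two_module_config()


@pytest.fixture(scope="session")
def small_trials(default_config):
    """A handful of default-condition trials shared across tests."""
    return generate_trials(default_config, 5, seed=11)


@pytest.fixture(scope="session")
def one_recording(default_config):
    return generate_recording(default_config, seed=7)


@pytest.fixture(scope="session")
def lowpass():
    return FilterSpec(kind="lowpass", corners=(2.0,), order=8)


@pytest.fixture
def grid_3x1():
    """A 1 x 3 line of electrodes for hand-traceable flood fills."""
    return ElectrodeLayout(1, 3)


@pytest.fixture
def grid_2x2():
    return ElectrodeLayout(2, 2)
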