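import numpy as np
import pytest

from sprisk.simulate import default_parameters


@pytest.fixture(scope="session")
def s1_params():
    """Scenario 1 generating parameters of the simulation study."""
    return default_parameters("S1")


@pytest.fixture(scope="session")
def s2_params():
    """Scenario 2 generating parameters of the simulation study."""
    return default_parameters("S2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230217)
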