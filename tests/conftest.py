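import numpy as np
import pytest

from nitracer.synthetic_data import default_design, initial_state


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def sandy(design):
    return design.soils[0]


@pytest.fixture(scope="session")
def loam(design):
    return design.soils[1]


@pytest.fixture(scope="session")
def sandy_init_states(sandy):
    return {"nh4": initial_state(sandy, "a"), "no3": initial_state(sandy, "b")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
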