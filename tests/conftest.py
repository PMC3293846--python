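import numpy as np
import pytest

from kindisc.models import TimeGrid, build_glyoxalase_model


@pytest.fixture(scope="session")
def model1():
    return build_glyoxalase_model(1)


@pytest.fixture(scope="session")
def model2():
    return build_glyoxalase_model(2)


@pytest.fixture(scope="session")
def design_grid():
    """The default design grid: 0-120 min, 121 equidistant points."""
    return TimeGrid(0.0, 1.0, 121)


@pytest.fixture(scope="session")
def red_dot_ic():
    """Initial conditions of the chosen discriminatory design solution."""
    return {"GSH": 0.221, "MGO": 0.441, "HTA": 0.0, "SDLGS": 0.0}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
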