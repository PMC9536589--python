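import numpy as np
import pytest

from filafrap import BleachGeometry, make_distribution


@pytest.fixture(scope="session")
def geom_plateau():
    """Bleach zone deep inside the placement interval (plateau conditions)."""
    return BleachGeometry(F=470.0, y0=200.0, y1=210.0)


@pytest.fixture(scope="session")
def geom_small():
    return BleachGeometry(F=100.0, y0=50.0, y1=60.0)


@pytest.fixture(scope="session")
def gamma_velocity():
    """Reference velocity law: gamma, mean 1 um/min, sd 0.25, capped at 40."""
    return make_distribution("gamma", mean=1.0, sd=0.25, cap=40.0)


@pytest.fixture(scope="session")
def dirac_length_10():
    return make_distribution("dirac", mean=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
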