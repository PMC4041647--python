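import numpy as np
import pytest

from palmland.economics import build_default_yield_curve, calibrate_costs
from palmland.landscape import LandscapeParams, generate_landscape


@pytest.fixture(scope="session")
def default_curve():
    return build_default_yield_curve()


@pytest.fixture(scope="session")
def calibrated_costs():
    return calibrate_costs()


@pytest.fixture(scope="session")
def small_stack():
    """A 60x60 noise-free synthetic floodplain shared across tests."""
    return generate_landscape((60, 60), LandscapeParams(), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
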