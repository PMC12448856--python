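import numpy as np
import pytest

from flipkin.mechanism import MechanismVariant, RateConstants
from flipkin.traces import InstrumentModel, REGIME_BALANCED, SpeciesResponses


@pytest.fixture
def reference_rates():
    """Representative rate set inside the characterised ranges:
    k1 = 3e9 M^-1 s^-1, K1 = 5e5 M^-1, K2 = 5, K3 = 3.75."""
    return RateConstants(k1=3e9, k_m1=6000.0, k2=500.0, k_m2=100.0, k3=15.0, k_m3=4.0)


@pytest.fixture
def responses():
    return SpeciesResponses.from_fold_changes(I0=1.0)


@pytest.fixture
def instrument():
    return InstrumentModel(dead_time=2.7e-3, regimes=REGIME_BALANCED, noise_sd=0.003)


@pytest.fixture
def three_step():
    return MechanismVariant.THREE_STEP


def pytest_configure(config):
    np.seterr(over="ignore")
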