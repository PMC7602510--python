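import numpy as np
import pytest

from mompdose import (ABT199, CRC0076, CRC0344, KineticParameters,
                      reference_parameters)
from mompdose.synthetic import random_profile


@pytest.fixture(scope="session")
def default_params():
    return KineticParameters()


@pytest.fixture(scope="session")
def reference_params():
    """Parameters with (k_act, k_oligo) calibrated to the PDX baselines."""
    return reference_parameters()


@pytest.fixture(scope="session")
def anchors():
    return CRC0076, CRC0344


@pytest.fixture(scope="session")
def abt199_10uM():
    return ABT199.at_dose(10000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20201014)


@pytest.fixture(scope="session")
def small_profiles():
    """Low-concentration random profiles whose stress doses are small
    enough for 1 nM grid-scan oracles."""
    rng = np.random.default_rng(42)
    return [random_profile(rng, f"oracle-{i:02d}") for i in range(20)]
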