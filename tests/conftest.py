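import numpy as np
import pytest

from crossbridge import Conditions, reference_parameters


@pytest.fixture(scope="session")
def params_E():
    return reference_parameters("E_twostep")


@pytest.fixture(scope="session")
def params_A():
    return reference_parameters("A_beforePS")


@pytest.fixture(scope="session")
def shortening_conditions():
    return Conditions(conc_Pi=0.5, conc_MgATP=5e-3, v=1000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
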