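import numpy as np
import pytest
from hypothesis import settings

from osseodebond.contact_law import AdhesiveFrictionParams, ContactLaw

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def table_params():
    """Coin-implant interface parameters (calibrated parameter set)."""
    return dict(a_s=22e-6, b_s=0.74, mu_ub=0.44, mu_b=0.3,
                t0=1.8e6, g0=66e-6, g_b=66e-6, eps_n=1.8e12, eps_t=1.8e12)


@pytest.fixture(scope="session")
def emc_params(table_params):
    return AdhesiveFrictionParams(law=ContactLaw.EMC, **table_params)


@pytest.fixture(scope="session")
def mc_params(table_params):
    return AdhesiveFrictionParams(law=ContactLaw.MC, **table_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
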