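import numpy as np
import pytest

from lbalink.lba import LbaParams, simulate_trials


@pytest.fixture(scope="session")
def ref_params():
    """A comfortably identifiable parameter set used across tests."""
    return LbaParams(v_c=3.0, v_e=1.0, A=0.8, k=0.7, t0=0.25)


@pytest.fixture(scope="session")
def ref_trials(ref_params):
    """200 simulated trials from ref_params (one participant)."""
    return simulate_trials(ref_params, 200, seed=123, participant="P001")


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
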