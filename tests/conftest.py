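import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dupdiv.classify import Thresholds
from dupdiv.evolve import PopulationState, SerialProtocol
from dupdiv.model_core import AlleleParams, Environment, MutationRates
from dupdiv.reporter import ReporterParams


@pytest.fixture
def alleles():
    return AlleleParams(beta_anc=1.0, beta_mut=20.0)


@pytest.fixture
def low_demand_env():
    return Environment(demand=4.0, r0=0.2, rmax=0.9, cost_per_copy=0.01)


@pytest.fixture
def reporter_params():
    return ReporterParams()


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def small_protocol():
    return SerialProtocol(carrying_capacity=1e6)


def make_state(kmax=20, **classes):
    """State with abundances given as {(k, m): n} via keyword 'k_m' pairs."""
    counts = np.zeros((kmax, kmax + 1))
    for key, n in classes.items():
        k, m = (int(x) for x in key.split("_"))
        counts[k - 1, m] = n
    return PopulationState(counts)


@pytest.fixture
def state_factory():
    return make_state
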