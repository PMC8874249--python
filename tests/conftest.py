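import numpy as np
import pytest

from bpaqivive import DoseEvent, default_parameters, simulate
from bpaqivive.params import load_priors
from bpaqivive.synthetic import sample_parameter_set


@pytest.fixture(scope="session")
def central_params():
    return default_parameters()


@pytest.fixture(scope="session")
def standard_sim(central_params):
    """One 100 ug/kg oral-dose simulation at central parameters."""
    return simulate(central_params, DoseEvent(100.0, 0.0, 0.1))


@pytest.fixture(scope="session")
def priors_table():
    return load_priors()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_parameter_sets(priors_table):
    """Twenty valid prior draws reused across property tests."""
    gen = np.random.default_rng(777)
    return [sample_parameter_set(gen, priors_table) for _ in range(20)]
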