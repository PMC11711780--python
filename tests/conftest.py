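import numpy as np
import pytest

from flowtwin.model import simulate
from flowtwin.parameters import default_parameters
from flowtwin.synthetic import ZERO_NOISE, draw_subject, observe


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def default_sim(default_params):
    """One converged cycle of the healthy default subject."""
    return simulate(default_params)


@pytest.fixture(scope="session")
def subject42():
    """A drawn ground-truth subject with a tightly converged simulation and
    its noise-free measurement bundle."""
    truth = draw_subject(42)
    sim = simulate(truth, periodicity_tol=1e-6, n_cycles_max=60)
    bundle = observe(truth, ZERO_NOISE, seed=1, truth_sim=sim)
    return truth, sim, bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
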