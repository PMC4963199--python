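import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ireskinetics import SpeciesState, default_observables, make_truth_from_tables

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_minus():
    """Ground-truth rate constants, no eEF2 preincubation."""
    return make_truth_from_tables(eEF2=False)


@pytest.fixture(scope="session")
def truth_plus():
    """Ground-truth rate constants with eEF2 preincubation."""
    return make_truth_from_tables(eEF2=True)


@pytest.fixture(scope="session")
def observables():
    return default_observables()


@pytest.fixture
def all_in_1():
    return SpeciesState.point(1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
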