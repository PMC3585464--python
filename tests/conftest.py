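import pytest

from pysubst import (fixture, ka_steady_state, realize, solve_steady_state,
                     toy_switch_values, transition_system)
from pysubst.fixtures import FUM_FROZEN
from pysubst.substitution import coefficient_matrix


@pytest.fixture(scope="session")
def omm1():
    return fixture("omm1")


@pytest.fixture(scope="session")
def omm1_system(omm1):
    return coefficient_matrix(*omm1)


@pytest.fixture(scope="session")
def fum1():
    return fixture("fum1")


@pytest.fixture(scope="session")
def fum1_solution(fum1):
    return solve_steady_state(*fum1)[0]


@pytest.fixture(scope="session")
def fum1_transition(fum1):
    model, _pm = fum1
    return transition_system(model, FUM_FROZEN)


@pytest.fixture(scope="session")
def fum1_ka(fum1_transition):
    return ka_steady_state(fum1_transition)


@pytest.fixture(scope="session")
def fum2_system():
    return coefficient_matrix(*fixture("fum2"))


@pytest.fixture(scope="session")
def switch():
    model, pm = fixture("toy_switch")
    solution = solve_steady_state(model, pm)[0]
    realization = realize(solution, toy_switch_values())
    return model, solution, realization
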