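import pytest

from precursorsets import Mode, SolverConfig
from precursorsets.fixtures import (
    make_coupled_outputs,
    make_dual_route,
    make_redundant_feeders,
    make_regenerating_cycle,
    make_two_reaction,
)


@pytest.fixture(scope="session")
def two_reaction():
    return make_two_reaction()


@pytest.fixture(scope="session")
def cycle():
    return make_regenerating_cycle()


@pytest.fixture(scope="session")
def dual_route():
    # build-time checklist disabled here; it is exercised in test_fixtures
    return make_dual_route(verify=False)


@pytest.fixture(scope="session")
def feeders5():
    return make_redundant_feeders(5, verify=False)


@pytest.fixture(scope="session")
def coupled4():
    return make_coupled_outputs(4, verify=False)


@pytest.fixture(scope="session")
def config():
    return SolverConfig()


@pytest.fixture(params=[Mode.ACCUMULATE, Mode.STEADY_STATE, Mode.MACHINERY_DUPLICATING])
def any_mode(request):
    return request.param


def sets_of(result):
    """Canonical view of an enumeration result: a set of frozensets."""
    return {frozenset(sol["sources"]) for sol in result.solutions}
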