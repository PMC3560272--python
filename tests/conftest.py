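import pytest

from emcut import fixtures as fx


@pytest.fixture
def toy_partition():
    return fx.toy_partition()


@pytest.fixture
def toy_meta():
    return fx.toy_metadata()


@pytest.fixture
def toy_rules():
    return fx.toy_rules()


@pytest.fixture
def feas_weights():
    return fx.toy_feasibility_weights()


@pytest.fixture
def uniform():
    return fx.uniform_weights()


@pytest.fixture
def survivor_partition():
    return fx.survivor_partition()


# the five reaction-level minimal cut sets of the 12-reaction example
TOY_MCS = {
    frozenset({"R2", "R9"}),
    frozenset({"R2", "R5", "R6"}),
    frozenset({"R2", "R5", "R10"}),
    frozenset({"R2", "R6", "R11"}),
    frozenset({"R2", "R10", "R11"}),
}


@pytest.fixture
def toy_mcs_sets():
    return set(TOY_MCS)
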