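import pytest

from balred import fixtures
from balred.network import ReactionSpec, build_complexes


@pytest.fixture(scope="session")
def toy():
    return fixtures.toy_network()


@pytest.fixture(scope="session")
def toy_numeric_kinetics():
    return fixtures.toy_kinetics(symbolic=False, seed=3)


@pytest.fixture(scope="session")
def growth():
    return fixtures.growth_network()


@pytest.fixture
def open_chain():
    """0 -> A -> 0: a single intermediate complex between exchanges."""
    return build_complexes(
        [
            ReactionSpec(id="in", substrates={}, products={"A": 1}, upper_bound=10.0),
            ReactionSpec(id="out", substrates={"A": 1}, products={}, upper_bound=10.0),
        ]
    )


@pytest.fixture
def dead_end_chain():
    """0 -> A -> B with no outlet for B: both reactions blocked."""
    return build_complexes(
        [
            ReactionSpec(id="in", substrates={}, products={"A": 1}, upper_bound=10.0),
            ReactionSpec(id="conv", substrates={"A": 1}, products={"B": 1}, upper_bound=10.0),
        ]
    )


@pytest.fixture
def through_chain():
    """0 -> A -> B -> 0: nothing blocked, interior complexes balanced."""
    return build_complexes(
        [
            ReactionSpec(id="in", substrates={}, products={"A": 1}, upper_bound=10.0),
            ReactionSpec(id="conv", substrates={"A": 1}, products={"B": 1}, upper_bound=10.0),
            ReactionSpec(id="out", substrates={"B": 1}, products={}, upper_bound=10.0),
        ]
    )
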