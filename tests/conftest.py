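from fractions import Fraction

import pytest

from strongcomm import CharacteristicFunction, GameParams
from strongcomm.fixtures import (
    EDGE_COUNT_PARAMS,
    example1_graph,
    random_digraph,
    two_pair_digraph,
)


@pytest.fixture(scope="session")
def example1():
    """(graph, cf) for the three-node single-edge instance, g = edge count."""
    return example1_graph()


@pytest.fixture(scope="session")
def example1_cf(example1):
    return example1[1]


@pytest.fixture(scope="session")
def two_pair_cf():
    g = two_pair_digraph(5, 1)
    return CharacteristicFunction.graphical(
        g, GameParams(beta=Fraction(1, 2), gamma=1))


def random_cf(n, seed, beta=Fraction(1, 2), gamma=1, density=0.5, max_w=6):
    """Graphical game on a seeded random digraph (helper, not a fixture)."""
    g = random_digraph(n, density=density, max_w=max_w, seed=seed)
    return CharacteristicFunction.graphical(g, GameParams(beta=beta, gamma=gamma))
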