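import io

import numpy as np
import pytest

from mmcd import Graph, karate_club, load_edge_list


@pytest.fixture
def barbell():
    """Two triangles {1,2,3} and {4,5,6} joined by the edge (3,4); m = 7."""
    text = "1 2\n1 3\n2 3\n3 4\n4 5\n4 6\n5 6\n"
    return load_edge_list(io.StringIO(text))


@pytest.fixture
def triangle():
    return load_edge_list(io.StringIO("1 2\n2 3\n1 3\n"))


@pytest.fixture(scope="session")
def karate():
    return karate_club()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_graph(rng, n, p=0.3):
    """Erdos-Renyi graph as a Graph, guaranteed at least one edge."""
    while True:
        mask = rng.random((n, n)) < p
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if mask[i, j]]
        if edges:
            return Graph(np.array(edges), n=n)


class StubRng:
    """Deterministic stand-in for numpy Generator in hand-traced tests."""

    def __init__(self, random_values=(), integer_values=(), permutations=()):
        self._random = list(random_values)
        self._integers = list(integer_values)
        self._perms = list(permutations)

    def random(self, size=None):
        if size is None:
            return self._random.pop(0)
        return np.array([self._random.pop(0) for _ in range(size)])

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def permutation(self, n):
        if self._perms:
            return np.asarray(self._perms.pop(0))
        return np.arange(n)
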