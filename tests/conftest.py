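import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from pggcoevo.graph import COOPERATE, DEFECT  # noqa: E402


class FakeRng:
    """Minimal stand-in for numpy.random.Generator with fixed draws.

    ``random`` returns ``random_value`` (1.0 by default, so any
    "draw < p" event never fires); ``integers`` returns
    ``integer_value`` (0 by default). ``shuffle`` is a no-op.
    """

    def __init__(self, random_value=1.0, integer_value=0):
        self.random_value = random_value
        self.integer_value = integer_value

    def random(self, size=None):
        if size is None:
            return self.random_value
        return np.full(size, self.random_value)

    def integers(self, low, high=None, size=None):
        span = np.asarray(low if high is None else high)
        out = np.minimum(self.integer_value, span - 1)
        if size is None and span.ndim == 0:
            return int(out)
        return np.broadcast_to(out, span.shape if size is None else size).copy()

    def shuffle(self, arr):
        return None


@pytest.fixture
def fake_rng_never():
    return FakeRng(random_value=1.0)


@pytest.fixture
def fake_rng_always():
    return FakeRng(random_value=0.0)


def build_graph(edges, strategies, payoffs=None, weights=0, n_nodes=None):
    """Small labelled population graph for hand-built fixtures."""
    g = nx.Graph()
    n = n_nodes if n_nodes is not None else len(strategies)
    g.add_nodes_from(range(n))
    for i in range(n):
        g.nodes[i]["strategy"] = strategies[i]
        g.nodes[i]["payoff"] = 0.0 if payoffs is None else float(payoffs[i])
    for e in edges:
        g.add_edge(*e, weight=weights)
    return g


@pytest.fixture
def two_player_cd():
    """Single edge, node 0 cooperates, node 1 defects."""
    return build_graph([(0, 1)], [COOPERATE, DEFECT])


@pytest.fixture
def star_graph():
    """Center 0 with three leaves, all cooperating."""
    return build_graph([(0, 1), (0, 2), (0, 3)], [COOPERATE] * 4)
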