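"""Population graph: construction, attributes, component queries.

The population is a simple undirected :class:`networkx.Graph` whose
nodes are players. Node attributes: ``strategy`` ("C"/"D") and
``payoff`` (float, units of the contribution cost). Edge attribute:
``weight`` (integer breaking weight in [0, m_max]). Node ids are the
integers 0..N-1 and are never renumbered, no matter how many edges are
broken or added.
"""

from __future__ import annotations

from enum import Enum

import networkx as nx
import numpy as np

COOPERATE = "C"
DEFECT = "D"


class Strategy(str, Enum):
    """The two pure strategies of the public goods game."""

    COOPERATE = "C"
    DEFECT = "D"


def as_strategy_label(s: "Strategy | str") -> str:
    """Normalize a strategy (enum or 'C'/'D' string) to its label."""
    label = s.value if isinstance(s, Strategy) else s
    if label not in (COOPERATE, DEFECT):
        raise ValueError(f"unknown strategy {s!r}")
    return label


def make_ring_lattice(N: int, k0: int, seed, init_coop_fraction: float = 0.5) -> nx.Graph:
    """Build the initial k0-regular ring lattice with random strategies.

    Node i is connected to i±1, ..., i±k0/2 (mod N). Strategies are
    i.i.d. cooperate with probability ``init_coop_fraction``; every
    payoff starts at 0 and every edge weight at 0.

    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if k0 % 2 != 0:
        raise ValueError(f"k0 must be even, got {k0}")
    if not 0 < k0 < N:
        raise ValueError(f"need 0 < k0 < N, got k0={k0}, N={N}")
    rng = np.random.default_rng(seed)
    g = nx.circulant_graph(N, range(1, k0 // 2 + 1))
    coop = rng.random(N) < init_coop_fraction
    for i in range(N):
        g.nodes[i]["strategy"] = COOPERATE if coop[i] else DEFECT
        g.nodes[i]["payoff"] = 0.0
    nx.set_edge_attributes(g, 0, "weight")
    return g


def largest_component(g: nx.Graph) -> set:
    """Vertex set of the largest connected component.

    Ties are broken by the smallest contained node id, so the "largest
    part of the network" is deterministic given the graph. An empty
    graph yields the empty set.
    """
    if g.number_of_nodes() == 0:
        return set()
    best = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    return set(best)


def neighbors(g: nx.Graph, x) -> set:
    """Neighbor set of node x (its size is the M_x of the payoff sums)."""
    if x not in g:
        raise KeyError(f"node {x!r} not in graph")
    return set(g.neighbors(x))


# ---------------------------------------------------------------------------
# array views used by the vectorized round computations


def strategy_array(g: nx.Graph) -> np.ndarray:
    """Boolean cooperation indicator indexed by node id 0..N-1."""
    N = g.number_of_nodes()
    return np.fromiter(
        (g.nodes[i]["strategy"] == COOPERATE for i in range(N)), bool, count=N
    )


def payoff_array(g: nx.Graph) -> np.ndarray:
    N = g.number_of_nodes()
    return np.fromiter((g.nodes[i]["payoff"] for i in range(N)), float, count=N)


def edge_array(g: nx.Graph) -> np.ndarray:
    """(E, 2) integer endpoint array, in the graph's edge order."""
    m = g.number_of_edges()
    if m == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.fromiter(
        (i for e in g.edges for i in e), np.int64, count=2 * m
    ).reshape(-1, 2)


def degree_array(g: nx.Graph, edges: np.ndarray | None = None) -> np.ndarray:
    if edges is None:
        edges = edge_array(g)
    return np.bincount(edges.ravel(), minlength=g.number_of_nodes())
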