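"""Public-goods payoffs: single groups, cumulative rounds, per-edge attribution.

A *group* is a focal node together with its neighbors; each group runs
one public goods game per round. A cooperator pays cost c = 1 into the
pool; the pool is multiplied by the gain factor r and split equally
among the g group members, so a member earns r*n_c/g, minus 1 if it
cooperated. A node's round payoff is the sum over its own group and
every neighbor-centered group it belongs to (degree + 1 games).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import COOPERATE, Strategy, as_strategy_label, edge_array, strategy_array

#: contribution cost of a cooperator; the model's unit of payoff
C_COST = 1.0


@dataclass(frozen=True)
class GroupView:
    """One centered public-goods group: the focal node and its neighbors."""

    center: int
    members: frozenset[int]
    g: int
    n_c: int

    def __post_init__(self) -> None:
        if self.g < 1 or not 0 <= self.n_c <= self.g:
            raise ValueError("inconsistent group counts")
        if self.center not in self.members:
            raise ValueError("center must belong to its own group")


def group_view(graph: nx.Graph, center: int) -> GroupView:
    members = {center} | set(graph.neighbors(center))
    n_c = sum(1 for m in members if graph.nodes[m]["strategy"] == COOPERATE)
    return GroupView(center, frozenset(members), len(members), n_c)


def single_group_payoff(s: "Strategy | str", n_c: int, g: int, r: float) -> float:
    """Payoff of one member of a single group game.

    A cooperator earns r*n_c/g - 1, a defector r*n_c/g (cost c = 1).
    """
    if g < 1:
        raise ValueError("group size must be >= 1")
    if not 0 <= n_c <= g:
        raise ValueError(f"need 0 <= n_c <= g, got n_c={n_c}, g={g}")
    coop = as_strategy_label(s) == COOPERATE
    if coop and n_c == 0:
        raise ValueError("a cooperating member implies n_c >= 1")
    share = r * n_c / g
    return share - C_COST if coop else share


def cumulative_payoff(graph: nx.Graph, x: int, r: float) -> float:
    """Round payoff of node x: the sum of Eq-(1)-style payoffs over the
    x-centered group and every neighbor-centered group. Isolated -> 0."""
    if x not in graph:
        raise KeyError(f"node {x!r} not in graph")
    nbrs = list(graph.neighbors(x))
    if not nbrs:
        return 0.0
    s_x = graph.nodes[x]["strategy"]
    total = 0.0
    for center in [x, *nbrs]:
        gv = group_view(graph, center)
        total += single_group_payoff(s_x, gv.n_c, gv.g, r)
    return total


def edge_payoff_pair(graph: nx.Graph, x: int, y: int, r: float) -> tuple[float, float]:
    """Payoffs inside the x-centered game attributable to edge x-y.

    First element: x's payoff from the edge (its share of y's possible
    contribution minus its own spread cost): (r*s_y - s_x)/g. Second:
    y's full payoff in the x-centered game, r*n_c/g - s_y. This is the
    unilateral static attribution used by the edge-breaking value.
    """
    if not graph.has_edge(x, y):
        raise ValueError(f"no edge ({x!r}, {y!r})")
    gv = group_view(graph, x)
    s_x = 1.0 if graph.nodes[x]["strategy"] == COOPERATE else 0.0
    s_y = 1.0 if graph.nodes[y]["strategy"] == COOPERATE else 0.0
    x_part = (r * s_y - s_x) / gv.g
    y_part = r * gv.n_c / gv.g - s_y
    return x_part, y_part


def compute_payoffs(coop: np.ndarray, edges: np.ndarray, r: float) -> np.ndarray:
    """Vectorized round payoffs for all nodes.

    Parameters
    ----------
    coop : (N,) boolean cooperation indicator
    edges : (E, 2) integer endpoints
    r : gain factor

    Let q_c = r*n_c(c)/g(c) be the per-member share of the group
    centered at c. Then pi_x = sum of q over the deg(x)+1 groups
    containing x, minus (deg(x)+1) if x cooperates; isolated nodes get 0.
    """
    N = coop.shape[0]
    sc = coop.astype(float)
    deg = np.bincount(edges.ravel(), minlength=N)
    n_c = sc.copy()
    if edges.size:
        np.add.at(n_c, edges[:, 0], sc[edges[:, 1]])
        np.add.at(n_c, edges[:, 1], sc[edges[:, 0]])
    gsize = deg + 1
    q = r * n_c / gsize
    pi = q.copy()
    if edges.size:
        np.add.at(pi, edges[:, 0], q[edges[:, 1]])
        np.add.at(pi, edges[:, 1], q[edges[:, 0]])
    pi -= sc * gsize
    pi[deg == 0] = 0.0
    return pi


def play_round(graph: nx.Graph, r: float) -> np.ndarray:
    """Play every centered group once and store payoffs on the graph.

    Strategies are frozen during the round. Returns the payoff array
    indexed by node id; the same values are written to the ``payoff``
    node attribute (0 for isolated nodes).
    """
    coop = strategy_array(graph)
    edges = edge_array(graph)
    pi = compute_payoffs(coop, edges, r)
    for i in range(graph.number_of_nodes()):
        graph.nodes[i]["payoff"] = float(pi[i])
    return pi
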