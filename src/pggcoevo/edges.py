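"""Edge dynamics: breaking rule, isolated rejoin, dominant reconnection.

Stage A (breaking): each round, every edge gets a *breaking value* —
the payoff its two endpoints derive from one another. A non-negative
value lowers the edge's integer *breaking weight* by 1 (floor 0); a
negative value raises it by 3 (ceiling m_max). The edge is then removed
with probability given by the Poisson CDF F(weight; lam), so repeatedly
unsatisfying edges (weight near m_max) break almost surely while
satisfied ones persist with the small residual probability F(0) =
exp(-lam).

Stage C (isolated rejoin): a degree-0 node that currently cooperates
reconnects to a random member of the largest component with probability
p_isolated; defecting isolates stay out of the game.

Stage B (dominant reconnection): cooperators with strictly positive
payoff inside the largest component each link to a random non-isolated
cooperator they are not yet connected to.

All additions respect the global edge cap; new edges start at weight 0.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.stats import poisson

from .graph import (
    COOPERATE,
    degree_array,
    edge_array,
    largest_component,
    payoff_array,
    strategy_array,
)
from .params import GameParams
from .payoff import edge_payoff_pair


def breaking_probability(w: int, lam: float) -> float:
    """Removal probability for an edge of weight w: the Poisson CDF
    F(w; lam) = sum_{m=0..w} exp(-lam) lam^m / m!  (nondecreasing in w)."""
    if w < 0:
        raise ValueError("weight must be >= 0")
    if lam <= 0:
        raise ValueError("lam must be positive")
    return float(poisson.cdf(w, lam))


def breaking_probability_table(m_max: int, lam: float) -> np.ndarray:
    """F(w; lam) for w = 0..m_max as an array (lookup table for the step)."""
    return poisson.cdf(np.arange(m_max + 1), lam)


def update_weight(w: int, value: float, m_max: int, zero_satisfies: bool = False) -> int:
    """One weight update: -1 for a satisfying value, +3 otherwise,
    clamped to [0, m_max].

    A strictly positive value always satisfies and a strictly negative
    one never does. Whether an exactly-zero value satisfies is set by
    ``zero_satisfies``: the default (False) treats an edge that earns
    its endpoints nothing as unsatisfying, so payoff-dead regions keep
    fragmenting; True freezes them (see GameParams docs).
    """
    if not 0 <= w <= m_max:
        raise ValueError(f"weight {w} outside [0, {m_max}]")
    if value > 0 or (value == 0 and zero_satisfies):
        return max(w - 1, 0)
    return min(w + 3, m_max)


def edge_breaking_value(
    graph: nx.Graph, x: int, y: int, r: float, mode: str = "edge_attributed"
) -> float:
    """Breaking value of edge (x, y): how much its endpoints earn from it.

    ``edge_attributed`` (default) symmetrizes the per-edge payoff
    attribution over both centered games: x's and y's payoffs within
    the x-centered game plus y's and x's payoffs within the y-centered
    game. ``node_total`` simply sums the endpoints' stored round
    payoffs pi_x + pi_y.
    """
    if not graph.has_edge(x, y):
        raise ValueError(f"no edge ({x!r}, {y!r})")
    if mode == "node_total":
        return graph.nodes[x]["payoff"] + graph.nodes[y]["payoff"]
    if mode != "edge_attributed":
        raise ValueError(f"unknown value_mode {mode!r}")
    x_part, y_in_x = edge_payoff_pair(graph, x, y, r)
    y_part, x_in_y = edge_payoff_pair(graph, y, x, r)
    return x_part + y_in_x + y_part + x_in_y


def _edge_values(
    graph: nx.Graph, edges: np.ndarray, r: float, mode: str
) -> np.ndarray:
    """Vectorized breaking values for all edges at once."""
    if mode == "node_total":
        pi = payoff_array(graph)
        return pi[edges[:, 0]] + pi[edges[:, 1]]
    sc = strategy_array(graph).astype(float)
    deg = degree_array(graph, edges)
    n_c = sc.copy()
    if edges.size:
        np.add.at(n_c, edges[:, 0], sc[edges[:, 1]])
        np.add.at(n_c, edges[:, 1], sc[edges[:, 0]])
    gsize = (deg + 1).astype(float)
    x, y = edges[:, 0], edges[:, 1]
    val = (r * sc[y] - sc[x]) / gsize[x] + (r * n_c[x] / gsize[x] - sc[y])
    val += (r * sc[x] - sc[y]) / gsize[y] + (r * n_c[y] / gsize[y] - sc[x])
    return val


def apply_edge_breaking(
    graph: nx.Graph, params: GameParams, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Stage A for every edge: value -> weight update -> removal draw.

    Weights are updated for all edges (including those about to break);
    each edge is then removed independently with probability
    F(new weight; lam). Returns the set of removed edges. The edge
    order (the graph's insertion order) is deterministic, so the whole
    stage is reproducible from the seed.
    """
    edges = edge_array(graph)
    if edges.size == 0:
        return set()
    values = _edge_values(graph, edges, params.r, params.value_mode)
    elist = list(graph.edges)
    w = np.fromiter(
        (graph.edges[e]["weight"] for e in elist), np.int64, count=len(elist)
    )
    satisfied = (values > 0) | ((values == 0) & params.zero_value_satisfies)
    new_w = np.where(satisfied, np.maximum(w - 1, 0), np.minimum(w + 3, params.m_max))
    table = breaking_probability_table(params.m_max, params.lam)
    draws = rng.random(len(elist))
    remove = draws < table[new_w]
    removed: set[tuple[int, int]] = set()
    for i, e in enumerate(elist):
        if remove[i]:
            removed.add(e)
        else:
            graph.edges[e]["weight"] = int(new_w[i])
    graph.remove_edges_from(removed)
    return removed


def dominant_nodes(graph: nx.Graph) -> set:
    """Cooperators with strictly positive round payoff inside the
    largest connected component."""
    comp = largest_component(graph)
    return {
        x
        for x in comp
        if graph.nodes[x]["strategy"] == COOPERATE and graph.nodes[x]["payoff"] > 0
    }


def reconnect_isolated(
    graph: nx.Graph, params: GameParams, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Stage C: each isolated cooperator rejoins the largest component
    with probability p_isolated, gaining one weight-0 edge to a random
    member — by default a random cooperative member when one exists
    (``params.isolated_target``). Isolated defectors stay out.
    Additions stop at the edge cap."""
    added: set[tuple[int, int]] = set()
    if graph.number_of_edges() >= params.edge_cap:
        return added
    isolated = sorted(x for x, d in graph.degree if d == 0)
    if not isolated:
        return added
    comp = sorted(largest_component(graph))
    pool = comp
    if params.isolated_target == "cooperator":
        coops = [c for c in comp if graph.nodes[c]["strategy"] == COOPERATE]
        pool = coops or comp
    for x in isolated:
        if graph.number_of_edges() >= params.edge_cap:
            break
        if graph.nodes[x]["strategy"] != COOPERATE:
            continue
        if rng.random() >= params.p_isolated:
            continue
        candidates = pool if x not in pool else [c for c in pool if c != x]
        if not candidates:
            continue
        target = candidates[int(rng.integers(len(candidates)))]
        graph.add_edge(x, target, weight=0)
        added.add((x, target))
    return added


def reconnect_dominant(
    graph: nx.Graph,
    params: GameParams,
    rng: np.random.Generator,
    dominant: set | None = None,
) -> set[tuple[int, int]]:
    """Stage B: dominant nodes, in seeded random order, each add one
    weight-0 edge to a uniformly chosen non-isolated cooperator that is
    not themselves and not already a neighbor. Stops at the edge cap."""
    added: set[tuple[int, int]] = set()
    if graph.number_of_edges() >= params.edge_cap:
        return added
    if dominant is None:
        dominant = dominant_nodes(graph)
    if not dominant:
        return added
    order = np.array(sorted(dominant))
    rng.shuffle(order)
    candidates = np.array(
        sorted(
            x
            for x, d in graph.degree
            if d > 0 and graph.nodes[x]["strategy"] == COOPERATE
        )
    )
    if candidates.size == 0:
        return added
    for x in order:
        x = int(x)
        if graph.number_of_edges() >= params.edge_cap:
            break
        target = None
        # rejection sampling stays uniform over the eligible set; fall
        # back to the explicit set difference for near-saturated nodes
        for _ in range(32):
            t = int(candidates[int(rng.integers(candidates.size))])
            if t != x and not graph.has_edge(x, t):
                target = t
                break
        else:
            eligible = [
                int(t) for t in candidates if t != x and not graph.has_edge(x, t)
            ]
            if eligible:
                target = eligible[int(rng.integers(len(eligible)))]
        if target is None:
            continue
        graph.add_edge(x, target, weight=0)
        added.add((x, target))
    return added
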