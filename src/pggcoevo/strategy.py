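"""Fermi-rule strategy dynamics.

After every round, each player picks one random reference neighbor and
adopts that neighbor's strategy with the Fermi probability

    W = 1 / (1 + exp(-(pi_y - pi_x) / k)),

a logistic function of the payoff difference scaled by the noise k.
All adoptions in a step are computed from the same pre-update snapshot
and applied simultaneously (strategies are frozen within a round).
The reference neighbors are the *pre-edge-update* neighbor sets, so a
player imitates the partners it actually just played with.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit

from .graph import COOPERATE, DEFECT, payoff_array


@dataclass(frozen=True)
class StrategyUpdate:
    """Record of one node's imitation attempt in a step."""

    node: int
    teacher: int | None
    adopt_prob: float
    adopted: bool


def fermi_probability(pi_x: float, pi_y: float, k_noise: float) -> float:
    """Probability that x adopts y's strategy given their payoffs.

    Computed as expit((pi_y - pi_x)/k), which is overflow-safe for any
    payoff gap. k_noise = 0 is the fully rational limit: 1 if pi_y >
    pi_x, 0.5 on ties, else 0.
    """
    if k_noise < 0:
        raise ValueError("k_noise must be >= 0")
    if k_noise == 0:
        if pi_y > pi_x:
            return 1.0
        return 0.5 if pi_y == pi_x else 0.0
    return float(expit((pi_y - pi_x) / k_noise))


def _fermi_vec(delta: np.ndarray, k_noise: float) -> np.ndarray:
    if k_noise == 0:
        return np.where(delta > 0, 1.0, np.where(delta == 0, 0.5, 0.0))
    return expit(delta / k_noise)


def update_strategies(
    graph: nx.Graph,
    reference_neighbors: Mapping[int, Sequence[int]],
    k_noise: float,
    rng: np.random.Generator,
    record: bool = True,
) -> list[StrategyUpdate]:
    """Synchronous Fermi update for every node with reference neighbors.

    Each such node draws one teacher uniformly from its reference set
    and adopts the teacher's (pre-update) strategy with the Fermi
    probability of their (this round's) payoffs. Nodes whose reference
    set is empty do not update. With ``record=False`` the returned list
    only contains the updates that actually flipped a strategy.
    """
    N = graph.number_of_nodes()
    learners = [x for x in range(N) if reference_neighbors.get(x)]
    if not learners:
        return []
    flat = np.concatenate([np.asarray(reference_neighbors[x]) for x in learners])
    sizes = np.fromiter(
        (len(reference_neighbors[x]) for x in learners), np.int64, count=len(learners)
    )
    offsets = np.concatenate(([0], np.cumsum(sizes[:-1])))
    teachers = flat[offsets + rng.integers(0, sizes)]
    pi = payoff_array(graph)
    learner_arr = np.asarray(learners)
    probs = _fermi_vec(pi[teachers] - pi[learner_arr], k_noise)
    adopted = rng.random(len(learners)) < probs
    # snapshot both sides before anything is applied
    old = [graph.nodes[x]["strategy"] for x in learners]
    teacher_strats = [graph.nodes[int(t)]["strategy"] for t in teachers]
    updates: list[StrategyUpdate] = []
    for i, x in enumerate(learners):
        flipped = bool(adopted[i]) and teacher_strats[i] != old[i]
        if record or flipped:
            updates.append(
                StrategyUpdate(x, int(teachers[i]), float(probs[i]), bool(adopted[i]))
            )
        if adopted[i]:
            graph.nodes[x]["strategy"] = teacher_strats[i]
    return updates


def refresh_isolated_strategies(graph: nx.Graph, rng: np.random.Generator) -> set:
    """Let every degree-0 node redraw its strategy uniformly at random.

    Fermi imitation is undefined without neighbors; this resampling is
    what lets an isolated player "choose to cooperate" in a new round
    and thereby become eligible to rejoin the network."""
    resampled = set()
    for x in sorted(x for x, d in graph.degree if d == 0):
        graph.nodes[x]["strategy"] = COOPERATE if rng.random() < 0.5 else DEFECT
        resampled.add(x)
    return resampled
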