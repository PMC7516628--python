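"""Simulation driver: Monte Carlo steps, full runs, replicate averaging.

One Monte Carlo step (MCS) executes, in order:

1. isolated nodes redraw their strategy (so they can choose to
   cooperate this round),
2. every centered group plays once and payoffs are stored,
3. the current neighbor sets are snapshotted as the Fermi reference,
4. stage A — edge breaking,
5. stage C — isolated cooperators rejoin the largest component,
6. stage B — dominant nodes add edges, up to the global edge cap,
7. one synchronous Fermi strategy update against the reference
   neighbors and this round's payoffs.

Which of stages A/B/C actually run is set by the mechanism variant;
isolated rejoins are processed before dominant additions so that
players re-entering the game are not crowded out of capped edge slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .edges import apply_edge_breaking, reconnect_dominant, reconnect_isolated
from .graph import make_ring_lattice
from .metrics import MetricsRecord, measure
from .params import GameParams, Variant
from .payoff import play_round
from .strategy import refresh_isolated_strategies, update_strategies

__all__ = [
    "RoundResult",
    "SimulationTrace",
    "ReplicateResult",
    "mcs_step",
    "run",
    "run_replicates",
    "stationary_summary",
    "replicate_seed",
]

#: steps entering the stationary average (tail of the trace)
STATIONARY_WINDOW = 10


@dataclass(frozen=True)
class RoundResult:
    """What happened in one Monte Carlo step."""

    payoffs: np.ndarray
    edges_removed: set
    edges_added_isolated: set
    edges_added_dominant: set
    strategy_flips: tuple[int, ...]


@dataclass
class SimulationTrace:
    """Metrics time series of one run (step 0 = initial state)."""

    params: GameParams
    seed: int
    records: list[MetricsRecord] = field(default_factory=list)
    snapshots: dict[int, nx.Graph] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(rec) for rec in self.records])


@dataclass
class ReplicateResult:
    """Replicate-averaged trace plus the individual traces."""

    params: GameParams
    base_seed: int
    averaged: pd.DataFrame
    traces: list[SimulationTrace]

    def stationary(self, window: int = STATIONARY_WINDOW) -> pd.Series:
        return stationary_summary(self.averaged, window)


def mcs_step(
    graph: nx.Graph, params: GameParams, rng: np.random.Generator
) -> RoundResult:
    """Advance the co-evolution by one Monte Carlo step (see module doc)."""
    if params.isolated_strategy == "resample":
        refresh_isolated_strategies(graph, rng)
    payoffs = play_round(graph, params.r)
    reference = {x: tuple(graph.neighbors(x)) for x in graph}
    removed: set = set()
    added_iso: set = set()
    added_dom: set = set()
    active = params.active_stages
    for stage in params.stage_order:
        if stage not in active:
            continue
        if stage == "A":
            removed = apply_edge_breaking(graph, params, rng)
        elif stage == "C":
            added_iso = reconnect_isolated(graph, params, rng)
        elif stage == "B":
            added_dom = reconnect_dominant(graph, params, rng)
    if params.update_mode == "sync":
        flips = tuple(
            u.node
            for u in update_strategies(
                graph, reference, params.k_noise, rng, record=False
            )
        )
    else:
        flips = _async_update(graph, reference, params.k_noise, rng)
    return RoundResult(payoffs, removed, added_iso, added_dom, flips)


def _async_update(graph, reference, k_noise, rng) -> tuple[int, ...]:
    """Asynchronous variant (sensitivity checks): nodes update one at a
    time in seeded random order; payoffs stay frozen at round values."""
    from .strategy import fermi_probability

    nodes = [x for x in sorted(reference) if reference[x]]
    order = np.array(nodes)
    rng.shuffle(order)
    flips = []
    for x in order:
        x = int(x)
        nbrs = reference[x]
        t = int(nbrs[int(rng.integers(len(nbrs)))])
        w = fermi_probability(
            graph.nodes[x]["payoff"], graph.nodes[t]["payoff"], k_noise
        )
        if rng.random() < w:
            if graph.nodes[x]["strategy"] != graph.nodes[t]["strategy"]:
                flips.append(x)
            graph.nodes[x]["strategy"] = graph.nodes[t]["strategy"]
    return tuple(flips)


def run(
    params: GameParams,
    steps: int,
    seed: int,
    snapshot_steps: tuple[int, ...] = (),
) -> SimulationTrace:
    """One full simulation: build the ring lattice, record metrics at
    step 0 and after each of ``steps`` Monte Carlo steps.

    The trace (and any requested graph snapshots) is a deterministic
    function of (params, seed).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    graph = make_ring_lattice(params.N, params.k0, rng, params.init_coop_fraction)
    trace = SimulationTrace(params=params, seed=seed)
    trace.records.append(measure(graph, 0, params.entropy_mode))
    if 0 in snapshot_steps:
        trace.snapshots[0] = graph.copy()
    for t in range(1, steps + 1):
        mcs_step(graph, params, rng)
        trace.records.append(measure(graph, t, params.entropy_mode))
        if t in snapshot_steps:
            trace.snapshots[t] = graph.copy()
    return trace


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed split from the base seed."""
    state = np.random.SeedSequence([base_seed, replicate]).generate_state(1)[0]
    return int(state >> 1)  # keep below 2**31


def run_replicates(
    params: GameParams, steps: int, n_rep: int, base_seed: int
) -> ReplicateResult:
    """Independent replicates with split seeds, plus their per-step mean."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    traces = [
        run(params, steps, replicate_seed(base_seed, i)) for i in range(n_rep)
    ]
    frames = []
    for i, tr in enumerate(traces):
        df = tr.to_frame()
        df.insert(0, "replicate", i)
        frames.append(df)
    stacked = pd.concat(frames, ignore_index=True)
    averaged = stacked.drop(columns="replicate").groupby("step", as_index=False).mean()
    return ReplicateResult(params, base_seed, averaged, traces)


def stationary_summary(averaged: pd.DataFrame, window: int = STATIONARY_WINDOW) -> pd.Series:
    """Mean of the final ``window`` steps of an averaged trace."""
    cols = [c for c in averaged.columns if c != "step"]
    return averaged.tail(window)[cols].mean()
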