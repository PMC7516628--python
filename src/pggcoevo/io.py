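"""Readers/writers for graph snapshots, metrics tables, and run manifests.

Two snapshot formats are supported: GraphML (carries the node
attributes ``strategy``/``payoff``/``degree`` and the edge ``weight``,
round-trips losslessly) and a whitespace-delimited edge list
(``u v weight`` per line, edges only). A plain two-column label file
(``node strategy``) can accompany an edge list so external graphs can
be fed to the metrics module.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import networkx as nx


@dataclasses.dataclass
class RunManifest:
    """Provenance of one invocation: enough to reproduce it exactly."""

    config: dict
    base_seed: int
    replicate_seeds: list[int]
    version: str
    created: str
    outputs: list[str]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def make_manifest(config: dict, base_seed: int, replicate_seeds, outputs) -> RunManifest:
    from . import __version__

    return RunManifest(
        config=config,
        base_seed=base_seed,
        replicate_seeds=[int(s) for s in replicate_seeds],
        version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=[str(o) for o in outputs],
    )


def export_snapshot(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write a graph snapshot; see module doc for what each format keeps."""
    if format == "graphml":
        write_graphml(graph, path)
    elif format == "edgelist":
        write_edge_list(graph, path)
    else:
        raise ValueError(f"unknown snapshot format {format!r}")


def write_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    for x in g.nodes:
        g.nodes[x].setdefault("strategy", "D")
        g.nodes[x]["payoff"] = float(g.nodes[x].get("payoff", 0.0))
        g.nodes[x]["degree"] = int(g.degree(x))
    for e in g.edges:
        g.edges[e]["weight"] = int(g.edges[e].get("weight", 0))
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path, node_type=int)
    for x in g.nodes:
        g.nodes[x]["payoff"] = float(g.nodes[x].get("payoff", 0.0))
    for e in g.edges:
        g.edges[e]["weight"] = int(g.edges[e].get("weight", 0))
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u} {v} {int(data.get('weight', 0))}\n")


def read_edge_list(path, num_nodes: int | None = None) -> nx.Graph:
    """Read a ``u v [weight]`` edge list. ``num_nodes`` adds the nodes
    0..num_nodes-1 up front so isolated nodes survive the round trip."""
    g = nx.Graph()
    if num_nodes is not None:
        g.add_nodes_from(range(num_nodes))
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            u, v = int(parts[0]), int(parts[1])
            w = int(parts[2]) if len(parts) > 2 else 0
            g.add_edge(u, v, weight=w)
    for x in g.nodes:
        g.nodes[x].setdefault("strategy", "D")
        g.nodes[x].setdefault("payoff", 0.0)
    return g


def write_strategy_labels(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for x in sorted(graph.nodes):
            fh.write(f"{x} {graph.nodes[x]['strategy']}\n")


def read_strategy_labels(path) -> dict[int, str]:
    labels: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[1] not in ("C", "D"):
                raise ValueError(f"bad strategy label {parts[1]!r}")
            labels[int(parts[0])] = parts[1]
    return labels


def apply_strategy_labels(graph: nx.Graph, labels: dict[int, str]) -> nx.Graph:
    for x, s in labels.items():
        if x in graph:
            graph.nodes[x]["strategy"] = s
    return graph
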