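"""Interaction-network cleaning, clustering centrality and gatekeeper calls.

The clustering centrality of a node i is

    C_i = 2 E_i / (k_i (k_i - 1))

where k_i is its degree and E_i the number of edges among its k_i neighbors.
A *gatekeeper* is a node whose neighborhood is a clique (C_i exactly 1) with
at least ``min_degree`` (default 2) neighbors: a low-degree bridge between
mutually connected hubs.  The C = 1 test uses integer arithmetic
(2 E_i == k_i (k_i - 1)), never floating point.  Nodes of degree < 2, for
which the formula is undefined, take C = 0 by convention and are excluded
from gatekeeper calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CleaningReport",
    "clean_network",
    "induce_subnetwork",
    "clustering_centrality",
    "find_gatekeepers",
    "neighbor_edge_closure",
    "largest_component",
]


@dataclass(frozen=True)
class CleaningReport:
    n_nodes: int
    n_edges: int
    duplicates_removed: int
    self_loops_removed: int


def clean_network(raw_edges: Iterable[tuple[str, str]]) -> tuple[nx.Graph, CleaningReport]:
    """Build a simple undirected graph from an edge list.

    (A, B) and (B, A) collapse to one edge; self-loops are dropped.  The
    report counts removals.  An empty input yields an empty network.
    """
    graph = nx.Graph()
    duplicates = 0
    self_loops = 0
    for row in raw_edges:
        a, b = row
        if not a or not b:
            raise ValidationError(f"empty node identifier in edge {row!r}")
        if a == b:
            self_loops += 1
            continue
        if graph.has_edge(a, b):
            duplicates += 1
            continue
        graph.add_edge(a, b)
    report = CleaningReport(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        duplicates_removed=duplicates,
        self_loops_removed=self_loops,
    )
    return graph, report


def induce_subnetwork(
    net: nx.Graph, genes: Sequence[str]
) -> tuple[nx.Graph, list[str]]:
    """Subgraph induced on ``genes`` ∩ nodes; unmapped genes are returned, not dropped silently."""
    present = [g for g in genes if g in net]
    unmapped = sorted(set(genes) - set(present))
    return net.subgraph(present).copy(), unmapped


def clustering_centrality(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree k, neighbor-edge count E and clustering centrality C.

    E is the number of triangles through the node (an exact integer); C is
    2E / (k(k-1)) for k >= 2 and 0 otherwise.  Rows are sorted by node id.
    """
    tri = nx.triangles(net)
    nodes = sorted(net.nodes())
    k = [net.degree(n) for n in nodes]
    e = [tri[n] for n in nodes]
    c = [2.0 * ei / (ki * (ki - 1)) if ki >= 2 else 0.0 for ki, ei in zip(k, e)]
    return pd.DataFrame({"node": nodes, "k": k, "E": e, "C": c})


def find_gatekeepers(records: pd.DataFrame, min_degree: int = 2) -> list[str]:
    """Nodes with C exactly 1 (2E == k(k-1), integer test) and k >= min_degree."""
    k = records["k"].to_numpy()
    e = records["E"].to_numpy()
    mask = (k >= min_degree) & (2 * e == k * (k - 1))
    return sorted(records.loc[mask, "node"])


def neighbor_edge_closure(
    net: nx.Graph, seeds: Iterable[str], order: int = 1
) -> tuple[set[tuple[str, str]], float]:
    """Edges incident to the seeds (order 1) or to seeds plus their neighbors (order 2).

    Returns the edge set (as sorted node pairs) and the fraction of all
    network edges it covers.
    """
    seeds = set(seeds)
    unknown = sorted(seeds - set(net.nodes()))
    if unknown:
        raise ValidationError(f"unknown seed nodes: {unknown}")
    if order not in (1, 2):
        raise ValidationError("order must be 1 or 2")
    frontier = set(seeds)
    if order == 2:
        for s in seeds:
            frontier.update(net[s])
    edges = {tuple(sorted((u, v))) for u, v in net.edges() if u in frontier or v in frontier}
    total = net.number_of_edges()
    coverage = len(edges) / total if total else 0.0
    return edges, coverage


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties break toward the component containing the lexicographically
    smallest node.  An empty network yields an empty network.
    """
    if net.number_of_nodes() == 0:
        return nx.Graph()
    best = min(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    return net.subgraph(best).copy()
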