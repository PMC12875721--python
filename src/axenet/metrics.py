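"""Descriptive network statistics: loop-inclusive edge density, degree
statistics and Newman-Girvan modularity.

Density here follows the loop-inclusive convention: the number of *distinct*
realised connections (edge presence, not weight) divided by the theoretical
maximum including self-connections -- ``n**2`` ordered pairs for a directed
graph, ``n*(n+1)/2`` unordered pairs for an undirected graph.  Both
conventions are exposed because published density values rarely state which
was used; the pipeline records the convention it applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .vocabulary import INCUBATION

CONVENTIONS = ("directed", "undirected")


def _method_nodes(graph: nx.Graph, node_subset: Iterable[str] | None) -> list[str]:
    if node_subset is None:
        nodes = [n for n in graph.nodes if n != INCUBATION]
    else:
        nodes = list(node_subset)
        missing = [n for n in nodes if n not in graph]
        if missing:
            raise ValueError(f"subset nodes not in graph: {missing}")
    if not nodes:
        raise ValueError("empty node set")
    return nodes


def edge_density(
    graph: nx.Graph | nx.DiGraph,
    node_subset: Iterable[str] | None = None,
    convention: str = "directed",
) -> float:
    """Loop-inclusive edge density of the (sub)graph on method nodes.

    ``convention="directed"`` counts ordered connections out of ``n**2``
    possibilities; ``"undirected"`` collapses antiparallel pairs and counts
    out of ``n*(n+1)/2``.  Edges touching the incubation sink are ignored.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown density convention {convention!r}")
    nodes = _method_nodes(graph, node_subset)
    node_set = set(nodes)
    n = len(nodes)
    connections: set[tuple[str, str]] = set()
    for u, v in graph.edges():
        if u not in node_set or v not in node_set:
            continue
        if convention == "directed" and graph.is_directed():
            connections.add((u, v))
        else:
            connections.add((min(u, v), max(u, v)))
    if convention == "directed":
        maximum = n * n
        if not graph.is_directed():  # each undirected edge realises both directions
            realised = sum(1 if a == b else 2 for a, b in connections)
            return realised / maximum
    else:
        maximum = n * (n + 1) // 2
    return len(connections) / maximum


def degree_stats(
    graph: nx.Graph | nx.DiGraph,
    node_subset: Iterable[str] | None = None,
) -> tuple[dict[str, int], float]:
    """Per-node degree and the median degree over the method nodes.

    Directed graphs use total degree (in + out); a self-loop contributes one
    to each of in- and out-degree (two to an undirected degree).  Edges to
    the incubation sink are excluded, matching the node set.
    """
    nodes = _method_nodes(graph, node_subset)
    sub = graph.subgraph(nodes)
    degrees = {n: int(sub.degree(n)) for n in nodes}
    return degrees, float(np.median(list(degrees.values())))


def modularity(
    graph: nx.Graph,
    partition: Mapping[str, int],
) -> float:
    """Newman-Girvan modularity Q of a partition of an undirected graph.

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]  with e_c the intra-community edge
    weight, d_c the summed degree of community c (loops counting twice) and m
    the total edge weight.  Q is 0 for the single-community partition and
    lies in [-1/2, 1].
    """
    nodes = list(graph.nodes)
    missing = [n for n in nodes if n not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    m = graph.size(weight="weight")
    if m <= 0:
        return 0.0
    communities = set(partition[n] for n in nodes)
    q = 0.0
    for c in communities:
        members = {n for n in nodes if partition[n] == c}
        e_c = sum(
            d.get("weight", 1)
            for u, v, d in graph.edges(members, data=True)
            if u in members and v in members
        )
        d_c = sum(graph.degree(n, weight="weight") for n in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


@dataclass(frozen=True)
class MetricsReport:
    """Descriptive statistics of one method network or cluster subgraph."""

    label: str
    n_nodes: int
    n_edges_actual: int
    density: float
    median_degree: float
    density_convention: str
    modularity_q: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_nodes": self.n_nodes,
            "n_edges_actual": self.n_edges_actual,
            "density": self.density,
            "median_degree": self.median_degree,
            "density_convention": self.density_convention,
            "modularity_q": self.modularity_q,
        }


def metrics_report(
    graph: nx.Graph | nx.DiGraph,
    label: str = "",
    node_subset: Iterable[str] | None = None,
    convention: str = "directed",
    modularity_q: float | None = None,
) -> MetricsReport:
    nodes = _method_nodes(graph, node_subset)
    node_set = set(nodes)
    n_edges = sum(1 for u, v in graph.edges() if u in node_set and v in node_set)
    _, med = degree_stats(graph, nodes)
    return MetricsReport(
        label=label,
        n_nodes=len(nodes),
        n_edges_actual=n_edges,
        density=edge_density(graph, nodes, convention=convention),
        median_degree=med,
        density_convention=convention,
        modularity_q=modularity_q,
    )
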