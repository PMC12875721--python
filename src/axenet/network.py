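"""Workflow-to-graph transformation.

Each species-level record lists its axenisation methods in application order
``m1 .. mk``.  The division's workflow network is the weighted directed graph
whose edges count ordered transitions ``m1->m2, .., m(k-1)->mk`` plus the
terminal transition ``mk->INCB`` into the incubation sink, across all records
of the division.  Consecutive repeats of a method create self-loops.  The
incubation sink is stored in the graph but excluded from the method node set
and from all metrics by convention, so that printed node counts refer to
methods only.

A second, undirected network captures how publications combine verification
(axenicity screening) methods: nodes are verification codes and an edge
weight counts the publications using both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .master_table import MasterTable
from .vocabulary import (
    INCUBATION,
    method_vocabulary,
    verification_vocabulary,
)


@dataclass(frozen=True)
class WorkflowNetwork:
    """Weighted directed method graph for one division, with incubation sink."""

    division: str
    graph: nx.DiGraph  # includes the INCB sink; edge attribute "weight"
    n_records: int

    @property
    def method_nodes(self) -> tuple[str, ...]:
        """Method nodes (the incubation sink excluded), sorted."""
        return tuple(sorted(n for n in self.graph.nodes if n != INCUBATION))

    @property
    def n_nodes(self) -> int:
        return len(self.method_nodes)

    def method_graph(self) -> nx.DiGraph:
        """Directed view restricted to method nodes (sink dropped)."""
        return self.graph.subgraph(self.method_nodes).copy()


def build_workflow_network(records, label: str) -> WorkflowNetwork:
    """Build a workflow network from an explicit record collection."""
    records = list(records)
    if not records:
        raise ValueError(f"no records for {label!r}")
    vocab = method_vocabulary()
    g = nx.DiGraph()
    for rec in records:
        for code in rec.methods:
            if code not in g:
                g.add_node(code, category=vocab[code].category)
        path = list(rec.methods) + [INCUBATION]
        for u, v in zip(path, path[1:]):
            w = g.get_edge_data(u, v, default={"weight": 0})["weight"]
            g.add_edge(u, v, weight=w + 1)
    g.add_node(INCUBATION, category="Sink")
    return WorkflowNetwork(division=label, graph=g, n_records=len(records))


def build_axenisation_network(table: MasterTable, division: str) -> WorkflowNetwork:
    """Build the division's workflow network from its species-level records.

    Raises ``ValueError`` when the division has no records: an empty network
    is meaningless (there is nothing to connect to incubation).
    """
    records = [r for r in table.records if r.division == division]
    if not records:
        raise ValueError(f"no records for division {division!r}")
    return build_workflow_network(records, division)


def to_undirected(
    net: WorkflowNetwork | nx.DiGraph,
    keep_loops: bool = False,
    weighted: bool = True,
) -> nx.Graph:
    """Undirected projection of a workflow network, incubation sink excluded.

    Antiparallel edge pairs collapse to one edge with summed weight; with
    ``weighted=False`` every surviving edge gets weight 1 (binarised view).
    """
    directed = net.graph if isinstance(net, WorkflowNetwork) else net
    und = nx.Graph()
    und.add_nodes_from(
        (n, d) for n, d in directed.nodes(data=True) if n != INCUBATION
    )
    for u, v, data in directed.edges(data=True):
        if INCUBATION in (u, v):
            continue
        if u == v and not keep_loops:
            continue
        w = und.get_edge_data(u, v, default={"weight": 0})["weight"]
        und.add_edge(u, v, weight=w + data.get("weight", 1))
    if not weighted:
        nx.set_edge_attributes(und, 1, "weight")
    return und


@dataclass(frozen=True)
class VerificationNetwork:
    """Publication-level co-usage network of verification methods."""

    graph: nx.Graph             # edge weight = publications using both methods
    usage: Mapping[str, int]    # verification code -> publications using it
    group_totals: Mapping[str, int]  # group -> publications using any member


def build_verification_network(table: MasterTable) -> VerificationNetwork:
    """Co-usage of verification methods, resolved at publication level."""
    vocab = verification_vocabulary()
    per_pub: dict[str, set[str]] = {}
    for rec in table.records:
        per_pub.setdefault(rec.publication_id, set()).update(rec.verification_methods)

    usage: dict[str, int] = {}
    group_totals: dict[str, int] = {}
    g = nx.Graph()
    for methods in per_pub.values():
        for code in methods:
            usage[code] = usage.get(code, 0) + 1
            if code not in g:
                group = vocab[code].group if code in vocab else "other"
                g.add_node(code, group=group)
        groups = {vocab[c].group for c in methods if c in vocab}
        for grp in groups:
            group_totals[grp] = group_totals.get(grp, 0) + 1
        for a, b in combinations(sorted(methods), 2):
            w = g.get_edge_data(a, b, default={"weight": 0})["weight"]
            g.add_edge(a, b, weight=w + 1)
    return VerificationNetwork(
        graph=g,
        usage=dict(sorted(usage.items())),
        group_totals=dict(sorted(group_totals.items())),
    )


def edge_list_rows(graph: nx.Graph | nx.DiGraph) -> list[tuple[str, str, int]]:
    """Sorted (source, target, weight) rows for CSV export."""
    return sorted(
        (u, v, int(d.get("weight", 1))) for u, v, d in graph.edges(data=True)
    )


def write_graphml(graph: nx.Graph | nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.Graph | nx.DiGraph, path) -> None:
    """Minimal DOT export (node category and edge weight attributes)."""
    directed = graph.is_directed()
    lines = ["digraph workflow {" if directed else "graph workflow {"]
    arrow = "->" if directed else "--"
    for n, data in sorted(graph.nodes(data=True)):
        attrs = "".join(f' {k}="{v}"' for k, v in sorted(data.items()))
        lines.append(f'  "{n}" [{attrs.strip()}];' if attrs else f'  "{n}";')
    for u, v, w in edge_list_rows(graph):
        lines.append(f'  "{u}" {arrow} "{v}" [weight={w}];')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
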