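"""Maximal clique enumeration and per-cluster largest cliques.

A clique of the undirected method graph is a set of methods that are all
pairwise connected -- methods reported in immediate succession with each
other.  Enumeration of maximal cliques uses the Bron-Kerbosch algorithm with
pivoting as implemented by :func:`networkx.find_cliques`; results are
canonicalised (members sorted, cliques in lexicographic order) so reports are
deterministic.  Cliques are an unweighted concept: weights and self-loops
are ignored, and the incubation sink is excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .clustering import Partition
from .vocabulary import INCUBATION


@dataclass(frozen=True)
class Clique:
    members: tuple[str, ...]
    cluster_id: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def _simple_view(graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(n for n in graph.nodes if n != INCUBATION)
    g.add_edges_from(
        (u, v) for u, v in graph.edges() if u != v and INCUBATION not in (u, v)
    )
    return g


def maximal_cliques(graph: nx.Graph) -> list[Clique]:
    """All maximal cliques of the simple undirected view, sorted.

    Isolated nodes are reported as singleton cliques (they are maximal).
    """
    g = _simple_view(graph)
    found = sorted(tuple(sorted(c)) for c in nx.find_cliques(g))
    return [Clique(members=c) for c in found]


def largest_cliques_in_cluster(
    graph: nx.Graph, partition: Partition
) -> dict[int, list[Clique]]:
    """Per community: all maximum-size cliques of the induced subgraph.

    Co-maximal cliques are all reported, ordered lexicographically, so a
    cluster may list several equally large cliques.
    """
    g = _simple_view(graph)
    missing = [n for n in g.nodes if n not in partition.assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    out: dict[int, list[Clique]] = {}
    for cid in sorted(set(partition.assignment.values())):
        members = [n for n, c in partition.assignment.items() if c == cid]
        sub = g.subgraph(members)
        cliques = sorted(tuple(sorted(c)) for c in nx.find_cliques(sub))
        if not cliques:
            continue
        top = max(len(c) for c in cliques)
        out[cid] = [Clique(members=c, cluster_id=cid) for c in cliques if len(c) == top]
    return out
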