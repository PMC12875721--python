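"""Modularity-maximising community detection, exact at small network sizes.

The method networks in this domain are small (at most ~20 method nodes), so
the globally optimal partition under Newman-Girvan modularity is computed by
branch-and-bound over restricted-growth assignments: nodes are assigned in
sorted label order to an existing community or a new one, and a subtree is
pruned when the partial modularity plus the sum of the remaining positive
pair terms cannot beat the incumbent.  Enumerating assignments in
lexicographic order and replacing the incumbent only on a strict improvement
makes the result the lexicographically smallest optimal assignment, hence
deterministic and independent of node insertion order.

For larger graphs a greedy agglomerative merge (best positive delta-Q merge
until none remains) is used instead.

Writing Q = sum_c [e_c/m - (d_c/2m)^2] and expanding over node pairs gives

    Q = C + sum_{i<j in same community} p_ij,
    p_ij = (w_ij - k_i k_j / 2m) / m,
    C    = sum_i w_ii / m - sum_i k_i^2 / (4 m^2),

so the search only has to maximise the sum of within-community pair terms;
the constant C collects the diagonal (self-pair and self-loop) terms.
Connected components are solved independently (an optimal community never
spans components, since merging across components can only lower Q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .metrics import modularity

DEFAULT_MAX_EXACT_N = 20


@dataclass(frozen=True)
class Partition:
    """Node -> community assignment with its modularity Q."""

    assignment: Mapping[str, int]
    q: float
    method: str  # "exact" or "greedy"

    def communities(self) -> list[tuple[str, ...]]:
        """Communities as sorted member tuples, ordered by community id."""
        groups: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, []).append(node)
        return [tuple(sorted(groups[cid])) for cid in sorted(groups)]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def _pair_terms(graph: nx.Graph, nodes: Sequence[str], m: float):
    """Pairwise modularity terms p_ij for the given node order."""
    idx = {n: i for i, n in enumerate(nodes)}
    k = np.array([graph.degree(n, weight="weight") for n in nodes], dtype=float)
    p = -np.outer(k, k) / (2.0 * m) / m
    for u, v, d in graph.edges(nodes, data=True):
        if u in idx and v in idx and u != v:
            i, j = idx[u], idx[v]
            p[i, j] += d.get("weight", 1) / m
            p[j, i] += d.get("weight", 1) / m
    return p


def _partition_score(p: np.ndarray, assignment: Sequence[int]) -> float:
    """Sum of within-community pair terms for an index assignment."""
    a = np.asarray(assignment)
    same = a[:, None] == a[None, :]
    return float(p[np.triu(same, k=1)].sum())


def _exact_component(graph: nx.Graph, nodes: list[str], m: float) -> list[int]:
    """Max-modularity assignment of one component, lexicographically smallest
    in the given node order.

    Branch-and-bound over restricted-growth strings.  The incumbent bound is
    seeded just below the greedy solution's score, so subtrees that cannot
    beat the greedy partition are pruned immediately while the search still
    returns the lexicographically first assignment attaining the optimum.
    """
    n = len(nodes)
    p = _pair_terms(graph, nodes, m)
    # pos_remaining[t]: upper bound on gain from pairs whose later node is >= t
    pos_remaining = np.zeros(n + 1)
    for t in range(n - 1, -1, -1):
        pos_remaining[t] = pos_remaining[t + 1] + np.sum(np.maximum(p[:t, t], 0.0))

    greedy = _greedy_component(graph, nodes, m)
    assignment = np.zeros(n, dtype=np.int64)
    best_assignment = list(greedy)
    best_score = _partition_score(p, greedy) - 1e-12

    def recurse(t: int, used: int, score: float) -> None:
        nonlocal best_score, best_assignment
        if score + pos_remaining[t] <= best_score:
            return
        if t == n:
            best_score = score
            best_assignment = assignment.tolist()
            return
        gains = np.bincount(assignment[:t], weights=p[:t, t], minlength=used) if t else np.zeros(0)
        for c in range(min(used + 1, n)):
            gain = gains[c] if c < used else 0.0
            if score + gain + pos_remaining[t + 1] <= best_score:
                continue
            assignment[t] = c
            recurse(t + 1, max(used, c + 1), score + gain)

    recurse(0, 0, 0.0)
    return best_assignment


def _greedy_component(graph: nx.Graph, nodes: list[str], m: float) -> list[int]:
    """Agglomerative best-merge assignment (merge while delta-Q > 0)."""
    n = len(nodes)
    p = _pair_terms(graph, nodes, m)
    comms: list[list[int]] = [[i] for i in range(n)]
    while len(comms) > 1:
        best_gain, best_pair = 0.0, None
        for a in range(len(comms)):
            for b in range(a + 1, len(comms)):
                gain = sum(p[i, j] for i in comms[a] for j in comms[b])
                if gain > best_gain + 1e-15:
                    best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        comms[a] = sorted(comms[a] + comms[b])
        del comms[b]
    assignment = [0] * n
    for cid, comm in enumerate(sorted(comms, key=min)):
        for i in comm:
            assignment[i] = cid
    return assignment


def _canonical(assignment: Mapping[str, int]) -> dict[str, int]:
    """Renumber community ids contiguously by first appearance in label order."""
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in sorted(assignment):
        cid = assignment[node]
        if cid not in remap:
            remap[cid] = len(remap)
        out[node] = remap[cid]
    return out


def optimal_partition(
    graph: nx.Graph,
    max_exact_n: int = DEFAULT_MAX_EXACT_N,
) -> Partition:
    """Modularity-maximising partition of an undirected (weighted) graph.

    Components with at most ``max_exact_n`` nodes are solved exactly by
    branch-and-bound; larger components fall back to greedy agglomeration
    (and the partition is labelled accordingly).  Isolated nodes and an
    edgeless graph yield singleton communities with Q = 0.
    """
    if graph.is_directed():
        raise ValueError("community detection expects an undirected graph")
    m = graph.size(weight="weight")
    assignment: dict[str, int] = {}
    method = "exact"
    if m <= 0:
        assignment = {n: i for i, n in enumerate(sorted(graph.nodes))}
        return Partition(_canonical(assignment), 0.0, "exact")

    next_id = 0
    components = sorted(nx.connected_components(graph), key=min)
    for comp in components:
        nodes = sorted(comp)
        if len(nodes) == 1:
            local = [0]
        elif len(nodes) <= max_exact_n:
            # High-degree nodes first: their pair terms are large, so partial
            # scores separate early and the bound prunes harder.
            by_degree = sorted(nodes, key=lambda n: (-graph.degree(n, weight="weight"), n))
            ordered = _exact_component(graph, by_degree, m)
            local = [ordered[by_degree.index(n)] for n in nodes]
        else:
            local = _greedy_component(graph, nodes, m)
            method = "greedy"
        for node, cid in zip(nodes, local):
            assignment[node] = next_id + cid
        next_id += max(local) + 1

    assignment = _canonical(assignment)
    return Partition(assignment, modularity(graph, assignment), method)


def compare_partitions(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    if set(a) != set(b):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a)
    return float(adjusted_rand_score([a[n] for n in nodes], [b[n] for n in nodes]))
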