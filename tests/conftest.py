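import numpy as np
import pytest

from axenet.master_table import Antibiotic, MasterTable, WorkflowRecord
from axenet.quality import RaterScores, RubricResponse
from axenet.synthetic import SyntheticConfig, generate_master_table

GOOD_RESPONSE = RubricResponse("yes", "yes", "yes", "multiple", "yes")
DEFAULT_QUALITY = RaterScores((GOOD_RESPONSE,) * 3)


def record(
    pub="pub001",
    species="Navicula sp-1",
    division="diatoms",
    methods=("Fltr", "Wash", "Mkpk"),
    outcome="success",
    year=2000,
    verification=(),
    antibiotics=(),
    quality=DEFAULT_QUALITY,
    media="f/2",
    habitat="marine",
    countries=("USA",),
):
    return WorkflowRecord(
        publication_id=pub,
        year=year,
        countries=frozenset(countries),
        division=division,
        species=species,
        habitat=habitat,
        media=media,
        methods=tuple(methods),
        outcome=outcome,
        verification_methods=frozenset(verification),
        antibiotics=tuple(antibiotics),
        quality=quality,
    )


def table(*records):
    return MasterTable(tuple(records))


@pytest.fixture
def make_record():
    return record


@pytest.fixture
def make_table():
    return table


@pytest.fixture(scope="session")
def synthetic_default():
    """Default-condition synthetic table with its ground-truth ledger."""
    return generate_master_table(SyntheticConfig(seed=7))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; used only to check the real code)

def iter_partitions(n):
    """All restricted-growth strings (set partitions as index assignments)."""
    def rec(prefix, used):
        if len(prefix) == n:
            yield list(prefix)
            return
        for c in range(used + 1):
            yield from rec(prefix + [c], max(used, c + 1))
    yield from rec([], 0)


def modularity_oracle(graph, labels):
    """Per-edge-sum Newman-Girvan Q, written independently of the package."""
    m = sum(d.get("weight", 1) for _, _, d in graph.edges(data=True))
    if m == 0:
        return 0.0
    q = 0.0
    for u, v, d in graph.edges(data=True):
        if labels[u] == labels[v]:
            q += d.get("weight", 1) / m
    for c in set(labels.values()):
        d_c = sum(
            graph.degree(n, weight="weight") for n in graph if labels[n] == c
        )
        q -= (d_c / (2 * m)) ** 2
    return q


def best_partition_oracle(graph):
    """Brute-force maximum-modularity search (feasible for n <= 8)."""
    nodes = sorted(graph.nodes)
    best_q, best = -np.inf, None
    for assignment in iter_partitions(len(nodes)):
        labels = dict(zip(nodes, assignment))
        q = modularity_oracle(graph, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def maximal_cliques_oracle(graph):
    """Subset enumeration with bitmask adjacency (feasible for n <= 12)."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in graph.edges():
        if u != v:
            adj[idx[u]] |= 1 << idx[v]
            adj[idx[v]] |= 1 << idx[u]
    n = len(nodes)
    cliques = []
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if not all(adj[i] & mask == mask & ~(1 << i) for i in members):
            continue  # not a clique
        # maximal: no outside vertex adjacent to every member
        if any(
            all(adj[j] >> i & 1 for i in members)
            for j in range(n)
            if not mask >> j & 1
        ):
            continue
        cliques.append(tuple(nodes[i] for i in members))
    return sorted(cliques)


def ari_oracle(a, b):
    """Adjusted Rand index by direct pair counting."""
    from math import comb

    nodes = sorted(a)
    n = len(nodes)
    pairs_both = pairs_a = pairs_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[nodes[i]] == a[nodes[j]]
            sb = b[nodes[i]] == b[nodes[j]]
            pairs_a += sa
            pairs_b += sb
            pairs_both += sa and sb
    total = comb(n, 2)
    expected = pairs_a * pairs_b / total
    max_index = (pairs_a + pairs_b) / 2
    if max_index == expected:
        return 1.0
    return (pairs_both - expected) / (max_index - expected)
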