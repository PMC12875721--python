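import random

import networkx as nx
import pytest

from axenet.master_table import MasterTable
from axenet.network import (
    build_axenisation_network,
    build_verification_network,
    to_undirected,
)
from axenet.vocabulary import INCUBATION

from conftest import record, table


class TestBuildNetwork:
    def test_single_record_edges(self):
        net = build_axenisation_network(table(record(methods=("Fltr", "Wash", "Mkpk"))), "diatoms")
        weights = {(u, v): d["weight"] for u, v, d in net.graph.edges(data=True)}
        assert weights == {
            ("Fltr", "Wash"): 1,
            ("Wash", "Mkpk"): 1,
            ("Mkpk", INCUBATION): 1,
        }
        assert net.n_nodes == 3  # incubation sink not counted

    def test_incoming_sink_weight_equals_record_count(self, synthetic_default):
        tbl, _ = synthetic_default
        net = build_axenisation_network(tbl, "green_algae")
        into_sink = sum(
            d["weight"] for _, v, d in net.graph.edges(data=True) if v == INCUBATION
        )
        assert into_sink == net.n_records

    def test_total_weight_equals_total_method_count(self, synthetic_default):
        tbl, _ = synthetic_default
        net = build_axenisation_network(tbl, "diatoms")
        total = sum(d["weight"] for _, _, d in net.graph.edges(data=True))
        assert total == sum(
            len(r.methods) for r in tbl.records if r.division == "diatoms"
        )

    def test_record_order_invariance(self, synthetic_default):
        tbl, _ = synthetic_default
        shuffled = list(tbl.records)
        random.Random(3).shuffle(shuffled)
        a = build_axenisation_network(tbl, "dinoflagellates").graph
        b = build_axenisation_network(MasterTable(tuple(shuffled)), "dinoflagellates").graph
        assert nx.utils.graphs_equal(a, b)

    def test_repeated_method_creates_self_loop(self):
        net = build_axenisation_network(table(record(methods=("Wash", "Wash"))), "diatoms")
        assert net.graph.has_edge("Wash", "Wash")

    def test_empty_division_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            build_axenisation_network(table(record(division="diatoms")), "other")

    def test_node_categories_attached(self):
        net = build_axenisation_network(table(record(methods=("AntB", "Mkpk"))), "diatoms")
        assert net.graph.nodes["AntB"]["category"] == "Chemical"
        assert net.graph.nodes["Mkpk"]["category"] == "Physical"


class TestToUndirected:
    def test_antiparallel_weights_sum(self):
        tbl = table(
            record(pub="p1", species="a", methods=("Fltr", "Wash")),
            record(pub="p1", species="b", methods=("Fltr", "Wash")),
            record(pub="p2", species="a", methods=("Wash", "Fltr")),
        )
        und = to_undirected(build_axenisation_network(tbl, "diatoms"))
        assert und["Fltr"]["Wash"]["weight"] == 3

    def test_loops_dropped_by_default_kept_on_request(self):
        net = build_axenisation_network(table(record(methods=("Wash", "Wash"))), "diatoms")
        assert not list(nx.selfloop_edges(to_undirected(net)))
        assert list(nx.selfloop_edges(to_undirected(net, keep_loops=True)))

    def test_sink_excluded_and_edge_count_not_larger(self, synthetic_default):
        tbl, _ = synthetic_default
        net = build_axenisation_network(tbl, "other")
        und = to_undirected(net)
        assert INCUBATION not in und
        assert und.number_of_edges() <= net.graph.number_of_edges()

    def test_unweighted_view_binarises(self, synthetic_default):
        tbl, _ = synthetic_default
        und = to_undirected(build_axenisation_network(tbl, "diatoms"), weighted=False)
        assert all(d["weight"] == 1 for _, _, d in und.edges(data=True))


class TestVerificationNetwork:
    def test_pairwise_edge_from_one_publication(self):
        tbl = table(record(verification=("Plate", "Sequ")))
        ver = build_verification_network(tbl)
        assert ver.graph["Plate"]["Sequ"]["weight"] == 1

    def test_publication_level_dedup_across_species(self):
        tbl = table(
            record(pub="p1", species="a", verification=("Plate", "Sequ")),
            record(pub="p1", species="b", verification=("Plate", "Sequ")),
        )
        ver = build_verification_network(tbl)
        assert ver.graph["Plate"]["Sequ"]["weight"] == 1
        assert ver.usage == {"Plate": 1, "Sequ": 1}

    def test_group_totals_count_publications(self):
        tbl = table(
            record(pub="p1", species="a", verification=("LMspy", "EMspy", "Plate")),
            record(pub="p2", species="a", verification=("CMspy",)),
            record(pub="p3", species="a", verification=("Sequ",)),
        )
        ver = build_verification_network(tbl)
        assert ver.group_totals == {"counting": 1, "microscopy": 2, "sequencing": 1}

    def test_symmetric_weights(self, synthetic_default):
        tbl, _ = synthetic_default
        g = build_verification_network(tbl).graph
        assert all(d["weight"] >= 1 for _, _, d in g.edges(data=True))
        assert not g.is_directed()
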