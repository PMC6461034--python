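"""Kinase-substrate network construction, layout, and serialization."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from inka import network, scoring
from inka.knowledgebases import KnowledgeBase


def small_kb():
    relations = pd.DataFrame(
        {
            "kinase_symbol": ["KINA", "KINA", "KINB", "GHOST"],
            "substrate_symbol": ["SUBX", "SUBX", "SUBX", "SUBX"],
            "position": [10, 10, 10, 10],
            "residue": ["Y", "Y", "Y", "Y"],
            "source": ["PSP", "NWK", "PSP", "PSP"],
            "prediction_score": [np.nan, 3.0, np.nan, np.nan],
        }
    )
    loops = pd.DataFrame({"gene_symbol": ["KINA"], "peptide_sequence": ["LOOPK"]})
    return KnowledgeBase(relations, loops, frozenset({"KINA", "KINB", "GHOST"}))


def small_merged():
    return pd.DataFrame(
        {
            "gene_symbol": ["KINA", "KINB", "SUBX"],
            "peptide_sequence": ["LOOPK", "PEPBK", "PEP1K"],
            "n_phospho": [1, 1, 1],
            "accession": ["A1", "A2", "A3"],
            "position": [400, 300, 10],
            "residue": ["Y", "Y", "Y"],
            "localization_probability": [0.9] * 3,
            "n_inferred_sites": [1, 1, 1],
            "s1": [5.0, 2.0, 3.0],
        }
    )


@pytest.fixture()
def built():
    merged, kb = small_merged(), small_kb()
    scores = scoring.score_sample(merged, kb, "s1")
    sub = scoring.substrate_site_evidence(merged, kb, "s1")
    pep = scoring.kinase_peptide_evidence(merged, kb, "s1")
    return network.build_network(scores, sub, pep, top_n=20)


class TestBuildNetwork:
    def test_observed_kinase_gets_hexagon_kind(self, built):
        assert built.nodes["KINA"]["kind"] == network.OBSERVED_KINASE
        assert built.nodes["KINA"]["has_activation_loop_site"]

    def test_unobserved_substrate_linked_kinase_is_inferred(self, built):
        # GHOST has substrate links but no phosphopeptide of its own
        assert built.nodes["GHOST"]["kind"] == network.INFERRED_KINASE
        assert built.has_edge("GHOST", "SUBX")

    def test_dual_source_link_becomes_one_edge_tagged_both(self, built):
        assert built.has_edge("KINA", "SUBX")
        edge = built.edges["KINA", "SUBX"]
        assert edge["source"] == "both"
        assert edge["color"] == "forestgreen"
        assert edge["weight"] == pytest.approx(3.0)

    def test_substrate_is_circle_node_and_no_orphans(self, built):
        assert built.nodes["SUBX"]["kind"] == network.SUBSTRATE
        for node, attrs in built.nodes(data=True):
            if attrs["kind"] == network.SUBSTRATE:
                assert built.in_degree(node) >= 1

    def test_every_edge_tail_is_a_kinase(self, built):
        for tail, _head in built.edges:
            assert built.nodes[tail]["kind"] in (
                network.OBSERVED_KINASE,
                network.INFERRED_KINASE,
            )

    def test_empty_scores_give_empty_network(self):
        empty = scoring.score_sample(small_merged().iloc[:0], small_kb(), "s1")
        graph = network.build_network(empty, pd.DataFrame(columns=["kinase_symbol"]))
        assert graph.number_of_nodes() == 0

    def test_top_n_restricts_edge_tails(self):
        merged, kb = small_merged(), small_kb()
        scores = scoring.score_sample(merged, kb, "s1")
        sub = scoring.substrate_site_evidence(merged, kb, "s1")
        pep = scoring.kinase_peptide_evidence(merged, kb, "s1")
        graph = network.build_network(scores, sub, pep, top_n=1, include_inferred=False)
        ranked = scores[scores["inka"] > 0].sort_values("inka", ascending=False)
        assert {t for t, _ in graph.edges} == {ranked.index[0]}


class TestLayout:
    def test_single_node_sits_at_origin(self):
        g = nx.DiGraph()
        g.add_node("K")
        pos = network.layout_fr(g, seed=0)
        assert pos == {"K": (0.0, 0.0)}

    def test_same_seed_gives_identical_coordinates(self, built):
        a = network.layout_fr(built.copy(), seed=4)
        b = network.layout_fr(built.copy(), seed=4)
        assert a == b

    def test_iteration_parameter_scales_with_node_count(self):
        g = nx.DiGraph()
        g.add_edges_from((f"N{i}", f"N{i + 1}") for i in range(9))
        assert g.number_of_nodes() == 10
        network.layout_fr(g, seed=0)
        assert g.graph["fr_niter"] == 1000
        assert g.graph["fr_area"] == pytest.approx(10 ** 1.8)
        assert g.graph["fr_repulse_rad"] == pytest.approx(10 ** 1.5)
        assert g.graph["fr_ncell"] == pytest.approx(10 ** 3)


class TestSerialization:
    def test_graphml_round_trip_preserves_everything(self, built, tmp_path):
        network.layout_fr(built, seed=1)
        path = tmp_path / "net.graphml"
        network.write_graphml(built, path)
        again = network.read_graphml(path)
        assert set(again.nodes) == set(built.nodes)
        assert set(again.edges) == set(built.edges)
        for node in built.nodes:
            for key, value in built.nodes[node].items():
                loaded = again.nodes[node][key]
                if isinstance(value, float):
                    assert loaded == pytest.approx(value)
                else:
                    assert loaded == value
        for edge in built.edges:
            for key, value in built.edges[edge].items():
                loaded = again.edges[edge][key]
                if isinstance(value, float):
                    assert loaded == pytest.approx(value)
                else:
                    assert loaded == value

    def test_tidy_tables(self, built, tmp_path):
        network.write_tables(built, tmp_path / "e.tsv", tmp_path / "n.tsv")
        edges = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        nodes = pd.read_csv(tmp_path / "n.tsv", sep="\t")
        assert len(edges) == built.number_of_edges()
        assert len(nodes) == built.number_of_nodes()
        assert {"kinase", "substrate", "weight", "source"}.issubset(edges.columns)
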