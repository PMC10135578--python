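"""Bipartite diseasome construction, degrees, clustering, PPI screening."""

import pytest

from ecm_diseasome import data_io
from ecm_diseasome.diseasome_network import (
    brute_force_clusters,
    build_bipartite,
    collagen_subnetwork,
    diseases_per_gene,
    gene_nodes,
    genes_per_disease,
    matrisome_ppi_pairs,
    shared_disease_clusters,
)
from ecm_diseasome.records import (
    AssociationSource,
    GeneDiseaseAssociation,
    PpiPair,
)


def assoc(gene, disease):
    return GeneDiseaseAssociation(gene, disease, AssociationSource.CURATED)


def graph_of(pairs):
    graph, _ = build_bipartite([assoc(g, d) for g, d in pairs])
    return graph


class TestBuild:
    def test_duplicate_collapses(self):
        graph, report = build_bipartite(
            [assoc("A", "d1"), assoc("A", "d1"), assoc("B", "d2")])
        assert graph.number_of_edges() == 2
        assert report.duplicates == 1

    def test_empty_input(self):
        graph, _ = build_bipartite([])
        assert graph.number_of_nodes() == 0

    def test_gene_equal_disease_rejected(self):
        graph, report = build_bipartite([assoc("weird", "weird")])
        assert report.rejected == 1 and graph.number_of_edges() == 0

    def test_biclique_closed_form(self):
        g, d = 5, 7
        graph, _ = build_bipartite([assoc(f"G{i}", f"dis {j}")
                                    for i in range(g) for j in range(d)])
        assert graph.number_of_nodes() == g + d
        assert graph.number_of_edges() == g * d

    def test_same_string_cannot_collide_across_sides(self):
        graph = graph_of([("A", "b"), ("B", "a")])
        # "a"/"b" as diseases and "A"/"B" as genes coexist after lowering:
        assert graph.number_of_nodes() == 4


class TestDegrees:
    def test_stickler_fixture_degree_six(self, fixture_dir):
        assocs, _ = data_io.read_association_table(fixture_dir["stickler"])
        graph, _ = build_bipartite(assocs)
        table = genes_per_disease(graph)
        assert table.iloc[0].disease == "stickler syndrome"
        assert table.iloc[0].degree == 6

    def test_ullrich_fixture_degree_four(self, fixture_dir):
        assocs, _ = data_io.read_association_table(fixture_dir["ullrich"])
        graph, _ = build_bipartite(assocs)
        assert genes_per_disease(graph).iloc[0].degree == 4

    def test_handshake_identity(self, tiny_dataset):
        assocs, _ = data_io.read_association_table(tiny_dataset.associations)
        graph, _ = build_bipartite(assocs)
        per_disease = genes_per_disease(graph)
        per_gene = diseases_per_gene(graph)
        assert (int(per_disease.degree.sum()) == graph.number_of_edges()
                == int(per_gene.degree.sum()))


class TestCollagenSubnetwork:
    def test_only_collagen_edges_survive(self, small_catalog):
        graph = graph_of([("COL1A1", "oi"), ("COL2A1", "stickler"),
                          ("FBN1", "marfan"), ("MMP2", "x")])
        sub = collagen_subnetwork(graph, small_catalog)
        names = {sub.nodes[n]["name"] for n in gene_nodes(sub)}
        assert names == {"COL1A1", "COL2A1"}

    def test_no_collagens_empty(self, small_catalog):
        graph = graph_of([("FBN1", "marfan")])
        assert collagen_subnetwork(graph, small_catalog).number_of_nodes() == 0

    def test_idempotent(self, small_catalog):
        graph = graph_of([("COL1A1", "oi"), ("FBN1", "marfan")])
        once = collagen_subnetwork(graph, small_catalog)
        twice = collagen_subnetwork(once, small_catalog)
        assert set(once.nodes) == set(twice.nodes)
        assert set(once.edges) == set(twice.edges)


class TestClusters:
    def test_identical_disease_sets_co_cluster(self):
        graph = graph_of([("A", "d1"), ("A", "d2"), ("B", "d1"), ("B", "d2")])
        clusters = shared_disease_clusters(graph, cut=0.3)
        assert clusters["A"] == clusters["B"]

    def test_disjoint_sets_separate(self):
        graph = graph_of([("A", "d1"), ("B", "d2")])
        clusters = shared_disease_clusters(graph, cut=0.3)
        assert clusters["A"] != clusters["B"]

    def test_two_planted_blocks_recovered(self):
        # two gene blocks sharing no diseases; within-block Jaccard >= 0.6
        pairs = []
        for g in ("A1", "A2", "A3"):
            pairs += [(g, "left 1"), (g, "left 2"), (g, "left 3")]
        pairs += [("A1", "left 4")]  # Jaccard(A1, A2) = 3/4
        for g in ("B1", "B2"):
            pairs += [(g, "right 1"), (g, "right 2")]
        graph = graph_of(pairs)
        clusters = shared_disease_clusters(graph, cut=0.5)
        assert clusters["A1"] == clusters["A2"] == clusters["A3"]
        assert clusters["B1"] == clusters["B2"]
        assert clusters["A1"] != clusters["B1"]
        assert clusters == brute_force_clusters(graph, cut=0.5)

    def test_invariant_to_input_order(self):
        pairs = [("A", "d1"), ("A", "d2"), ("B", "d1"), ("C", "d9")]
        forward = shared_disease_clusters(graph_of(pairs), cut=0.4)
        backward = shared_disease_clusters(graph_of(list(reversed(pairs))), cut=0.4)
        assert forward == backward

    def test_invalid_cut_rejected(self):
        graph = graph_of([("A", "d1")])
        with pytest.raises(ValueError):
            shared_disease_clusters(graph, cut=1.5)


class TestPpiScreen:
    def test_both_endpoints_must_be_matrisome(self, small_catalog):
        pairs = [PpiPair.make("COL1A1", "FBN1"), PpiPair.make("COL1A1", "TP53")]
        result = matrisome_ppi_pairs(pairs, small_catalog)
        assert result.n_pairs == 1
        assert result.unique_genes == {"COL1A1", "FBN1"}

    def test_empty(self, small_catalog):
        result = matrisome_ppi_pairs([], small_catalog)
        assert result.n_pairs == 0 and result.n_genes == 0

    def test_planted_survivors_recovered(self, tiny_dataset):
        catalog, _ = data_io.read_matrisome_list(tiny_dataset.matrisome)
        pairs, _ = data_io.read_ppi_table(tiny_dataset.ppi)
        result = matrisome_ppi_pairs(pairs, catalog)
        manifest = tiny_dataset.manifest["ppi"]
        assert result.n_pairs == manifest["matrisome_pairs"]
        assert result.n_genes == manifest["matrisome_unique_genes"]
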