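"""Property-based invariants across modules (hypothesis, derandomized)."""

from collections import Counter

import pandas as pd
from hypothesis import given, strategies as st

from ecm_diseasome import data_io
from ecm_diseasome.disease_categorization import CategoryTerms, categorize_disease, category_counts
from ecm_diseasome.diseasome_network import build_bipartite, diseases_per_gene, genes_per_disease
from ecm_diseasome.phewas_analysis import filter_by_p, top_hits
from ecm_diseasome.records import AssociationSource, GeneDiseaseAssociation, PhewasHit
from ecm_diseasome.variant_analysis import (
    AA_1TO3,
    AminoAcid,
    Missense,
    parse_protein_change,
    triplet_position,
)

residues = st.sampled_from(sorted(set(AA_1TO3) - {"*"}))
missenses = st.tuples(residues, residues, st.integers(1, 9999)).filter(
    lambda t: t[0] != t[1]).map(
    lambda t: Missense(AminoAcid(t[0]), t[2], AminoAcid(t[1])))

genes = st.sampled_from(["COL1A1", "COL2A1", "FBN1", "MMP2", "TP53", "ACAN"])
disease_names = st.sampled_from(["eds", "marfan syndrome", "oi", "alport syndrome", "x y"])
assoc_lists = st.lists(
    st.builds(GeneDiseaseAssociation, gene_symbol=genes, disease=disease_names,
              source=st.just(AssociationSource.CURATED)),
    max_size=30)


@given(missenses)
def test_parse_render_parse_identity(missense):
    """Rendering a missense and re-parsing it reproduces the event."""
    result = parse_protein_change(missense.render(),
                                  stop_gain_is_missense=True)
    assert result.is_missense
    assert result.missense == missense


@given(st.integers(1, 3000), st.integers(1, 50), st.sampled_from([0, 1, 2]))
def test_triplet_periodicity(offset_pos, helix_start, offset):
    """Positions p and p + 3 always occupy the same triplet slot."""
    p = helix_start + offset_pos
    a = triplet_position(p, helix_start, offset)
    b = triplet_position(p + 3, helix_start, offset)
    assert a == b


@given(assoc_lists)
def test_handshake_identity(assocs):
    """Degree sums on both sides equal the edge count for any graph."""
    graph, _ = build_bipartite(assocs)
    per_disease = genes_per_disease(graph)
    per_gene = diseases_per_gene(graph)
    assert (int(per_disease.degree.sum()) == graph.number_of_edges()
            == int(per_gene.degree.sum()))


@given(assocs=assoc_lists)
def test_association_round_trip_multiset(tmp_path_factory, assocs):
    """write -> read reproduces the deduplicated association multiset."""
    path = tmp_path_factory.mktemp("rt") / "a.tsv"
    unique = list({(a.gene_symbol, a.disease, a.source): a for a in assocs}.values())
    data_io.write_association_table(unique, path)
    back, _ = data_io.read_association_table(path)
    assert Counter(a.pair for a in back) == Counter(a.pair for a in unique)


@given(rows=st.lists(st.tuples(genes, st.text("abcdefgh ", min_size=1, max_size=8),
                               disease_names), max_size=25),
       order=st.permutations(range(25)))
def test_reader_dedup_order_independent(tmp_path_factory, rows, order):
    """Shuffling input rows never changes the loaded record multiset."""
    base = tmp_path_factory.mktemp("shuf")
    shuffled = [rows[i] for i in order if i < len(rows)]
    for name, data in (("a.tsv", rows), ("b.tsv", shuffled)):
        pd.DataFrame(data, columns=["gene", "variant_id", "condition"]).to_csv(
            base / name, sep="\t", index=False)
    first, _ = data_io.read_variant_table(base / "a.tsv")
    second, _ = data_io.read_variant_table(base / "b.tsv")
    assert Counter(first) == Counter(second)


@given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=0, max_size=60),
       st.floats(0.001, 1.0), st.floats(0.001, 1.0))
def test_filter_monotone_in_alpha(ps, a1, a2):
    hits = [PhewasHit(f"rs{i}", "G", f"ph{i}", "c", p) for i, p in enumerate(ps)]
    lo, hi = sorted((a1, a2))
    assert {h.snp_id for h in filter_by_p(hits, lo)} <= \
           {h.snp_id for h in filter_by_p(hits, hi)}


@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40),
       st.integers(1, 20))
def test_top_hits_nested(ps, n):
    hits = [PhewasHit(f"rs{i}", "G", f"ph{i}", "c", p) for i, p in enumerate(ps)]
    smaller = [(h.snp_id, h.phenotype) for h in top_hits(hits, n)]
    larger = [(h.snp_id, h.phenotype) for h in top_hits(hits, n + 1)]
    assert set(smaller) <= set(larger)


@given(st.lists(disease_names, max_size=30))
def test_category_counts_partition(names):
    """Label counts always partition the assignment list."""
    terms = CategoryTerms.from_lists(["alport", "marfan", "eds"], ["x y"], ["oi"])
    assignments = [categorize_disease(n, terms) for n in names]
    table, marginals = category_counts(assignments, weight="by_association")
    assert int(table["count"].sum()) == len(assignments)
    label_counts = dict(zip(table["label"], table["count"]))
    for key in ("A", "B", "C"):
        assert marginals[key] == sum(
            count for label, count in label_counts.items()
            if key in label.split("_"))
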