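"""Reader/writer contracts: normalization, dedup, load-report conservation."""

import pandas as pd
import pytest

from ecm_diseasome import data_io
from ecm_diseasome.records import AssociationSource, Division, GeneDiseaseAssociation, PpiPair


def write_tsv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


class TestMatrisomeList:
    def test_duplicate_row_collapses(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv", [
            ("COL1A1", "core_matrisome", "collagens"),
            ("COL1A1", "core_matrisome", "collagens"),
            ("FBN1", "core_matrisome", "glycoproteins"),
            ("MMP2", "matrisome_associated", "ecm_regulators"),
            ("TGFB1", "matrisome_associated", "secreted_factors"),
        ], ["symbol", "division", "category"])
        catalog, report = data_io.read_matrisome_list(path)
        assert len(catalog) == 4
        assert report.dropped == 1
        report.check_conservation()

    def test_symbol_normalized_and_division_inferred(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv",
                         [(" col2a1 ", "Collagens")], ["symbol", "category"])
        catalog, _ = data_io.read_matrisome_list(path)
        gene = catalog["COL2A1"]
        assert gene.division is Division.CORE_MATRISOME

    def test_missing_column_names_it(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv", [("COL1A1",)], ["symbol"])
        with pytest.raises(data_io.FormatError, match="category"):
            data_io.read_matrisome_list(path)

    def test_conflicting_category_raises(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv", [
            ("COL1A1", "collagens"), ("COL1A1", "glycoproteins")],
            ["symbol", "category"])
        with pytest.raises(data_io.CatalogConflictError, match="COL1A1"):
            data_io.read_matrisome_list(path)

    def test_generated_catalog_proportions_recovered(self, tiny_dataset):
        catalog, _ = data_io.read_matrisome_list(tiny_dataset.matrisome)
        manifest = tiny_dataset.manifest["matrisome"]
        assert len(catalog) == manifest["n_matrisome"]
        from collections import Counter
        observed = Counter(g.category.value for g in catalog)
        assert dict(observed) == {k: v for k, v in manifest["category_counts"].items() if v}


class TestVariantTable:
    def test_empty_gene_dropped_and_counted(self, tmp_path):
        path = write_tsv(tmp_path / "v.tsv", [
            ("COL1A1", "rs1", "p.Gly661Arg", "EDS"),
            ("", "rs2", "", "EDS"),
            ("FBN1", "rs3", "", "Marfan syndrome")],
            ["gene", "variant_id", "protein_change", "condition"])
        records, report = data_io.read_variant_table(path)
        assert len(records) == 2
        assert report.dropped == 1

    def test_absent_protein_change_column(self, tmp_path):
        path = write_tsv(tmp_path / "v.tsv", [("COL1A1", "rs1", "EDS")],
                         ["gene", "variant_id", "condition"])
        records, _ = data_io.read_variant_table(path)
        assert records[0].protein_change is None

    def test_header_only_file_warns_empty(self, tmp_path):
        path = write_tsv(tmp_path / "v.tsv", [],
                         ["gene", "variant_id", "condition"])
        records, report = data_io.read_variant_table(path)
        assert records == []
        assert any("empty" in m for m in report.messages)

    def test_planted_duplicates_removed(self, tiny_dataset):
        records, report = data_io.read_variant_table(tiny_dataset.variants)
        manifest = tiny_dataset.manifest["variants"]
        assert report.rows_in == manifest["rows_written"]
        assert len(records) == manifest["unique_records"]
        # both polymorphism counts exposed
        assert report.extra["polymorphism_rows"] >= report.extra["unique_variant_ids"]


class TestPhewasTable:
    def test_scientific_notation_and_rejection(self, tmp_path):
        path = write_tsv(tmp_path / "p.tsv", [
            ("rs1", "TNXB", "celiac disease", "digestive", "5e-8"),
            ("rs2", "TNXB", "neuropathy", "neurological", "0.03"),
            ("rs3", "EYS", "bad", "none", "1.5"),
            ("rs4", "EYS", "worse", "none", "not-a-p")],
            ["snp", "gene", "phenotype", "category", "p"])
        hits, report = data_io.read_phewas_table(path)
        assert [h.p_value for h in hits] == [5e-8, 0.03]
        assert report.rejected == 2
        report.check_conservation()

    def test_generated_invalid_rows_rejected(self, tiny_dataset):
        hits, report = data_io.read_phewas_table(tiny_dataset.phewas)
        manifest = tiny_dataset.manifest["phewas"]
        assert report.rejected == manifest["invalid_p_rows"]
        assert len(hits) == manifest["valid_rows"]


class TestPpiTable:
    def test_unordered_pair_canonicalization(self, tmp_path):
        path = write_tsv(tmp_path / "ppi.tsv",
                         [("COL1A1", "FBN1"), ("FBN1", "COL1A1")],
                         ["gene_a", "gene_b"])
        pairs, report = data_io.read_ppi_table(path)
        assert pairs == [PpiPair("COL1A1", "FBN1")]
        assert report.dropped == 1

    def test_self_interaction_rejected(self, tmp_path):
        path = write_tsv(tmp_path / "ppi.tsv", [("COL1A1", "COL1A1")],
                         ["gene_a", "gene_b"])
        pairs, report = data_io.read_ppi_table(path)
        assert pairs == [] and report.rejected == 1


class TestAssociationRoundTrip:
    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "a.tsv"
        data_io.write_association_table([], path)
        assert path.read_text().strip() == "gene\tdisease\tsource"

    def test_round_trip_identity_and_sorted(self, tmp_path):
        assocs = [
            GeneDiseaseAssociation("FBN1", "marfan syndrome", AssociationSource.CURATED),
            GeneDiseaseAssociation("COL1A1", "osteogenesis imperfecta", AssociationSource.CURATED),
            GeneDiseaseAssociation("COL1A1", "eds", AssociationSource.CURATED),
        ]
        path = tmp_path / "a.tsv"
        data_io.write_association_table(assocs, path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame["gene"]) == sorted(frame["gene"])
        back, _ = data_io.read_association_table(path)
        assert sorted(a.pair for a in back) == sorted(a.pair for a in assocs)

    def test_dialect_column_mapping(self, tmp_path):
        path = write_tsv(tmp_path / "a.tsv", [("FBN1", "Marfan Syndrome ")],
                         ["GeneSymbol", "DiseaseName"])
        dialect = data_io.Dialect(columns={"gene": "GeneSymbol", "disease": "DiseaseName"})
        records, _ = data_io.read_association_table(path, dialect)
        assert records[0].pair == ("FBN1", "marfan syndrome")
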