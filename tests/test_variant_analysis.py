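"""HGVS protein-change parsing, substitution matrices, Gly-X-Y periodicity."""

import pytest

from ecm_diseasome import data_io
from ecm_diseasome.records import VariantRecord
from ecm_diseasome.variant_analysis import (
    ParseOutcome,
    parse_protein_change,
    rank_substituted,
    rank_targets,
    substitution_matrix,
    triplet_position,
    variants_per_disease,
)


def vrec(gene, vid, change, condition="some disease"):
    return VariantRecord(gene, vid, change, condition)


class TestParse:
    @pytest.mark.parametrize("text,ref,pos,alt", [
        ("p.Gly661Arg", "Gly", 661, "Arg"),
        ("p.Gly852Arg", "Gly", 852, "Arg"),
        ("p.Gly325Arg", "Gly", 325, "Arg"),
        ("G661R", "Gly", 661, "Arg"),
        ("gly661arg", "Gly", 661, "Arg"),      # three-letter, case-insensitive
        ("p.(Pro12Leu)", "Pro", 12, "Leu"),
        ("Xaa5Arg", "Xaa", 5, "Arg"),
    ])
    def test_missense_forms(self, text, ref, pos, alt):
        result = parse_protein_change(text)
        assert result.outcome is ParseOutcome.MISSENSE
        missense = result.missense
        assert (missense.ref.code3, missense.position, missense.alt.code3) == (ref, pos, alt)

    @pytest.mark.parametrize("text,kind", [
        ("p.Gly661=", "synonymous"),
        ("p.Trp26Ter", "stop_gain"),
        ("W26*", "stop_gain"),
        ("p.Val7fs", "fs"),
        ("p.Lys9del", "del"),
        ("p.Lys9dup", "dup"),
        ("p.Gly661Gly", "synonymous"),
    ])
    def test_not_missense(self, text, kind):
        result = parse_protein_change(text)
        assert result.outcome is ParseOutcome.NOT_MISSENSE
        assert result.kind == kind

    @pytest.mark.parametrize("text", ["", None, "c.1981G>A", "p.Zzz12Arg", "nonsense"])
    def test_unparseable(self, text):
        assert parse_protein_change(text).outcome is ParseOutcome.UNPARSEABLE

    def test_stop_gain_config_switch(self):
        result = parse_protein_change("p.Trp26Ter", stop_gain_is_missense=True)
        assert result.is_missense and result.missense.alt.code3 == "Ter"

    def test_render_canonical_round_trip(self):
        result = parse_protein_change("G661R")
        rendered = result.missense.render()
        assert rendered == "p.Gly661Arg"
        assert parse_protein_change(rendered).missense == result.missense


class TestSubstitutionMatrix:
    def test_counts_and_total(self):
        records = [vrec("COL3A1", "rs1", "p.Gly661Arg"),
                   vrec("COL4A5", "rs2", "p.Gly325Arg")]
        matrix = substitution_matrix(records)
        assert matrix["Gly", "Arg"] == 2
        assert matrix.total == 2

    def test_empty_input_all_zero(self):
        assert substitution_matrix([]).total == 0

    def test_diagonal_is_zero(self):
        matrix = substitution_matrix([vrec("G", "rs1", "p.Gly661Gly")])
        assert matrix.total == 0

    def test_gene_filter(self):
        records = [vrec("COL1A1", "rs1", "p.Gly10Arg"), vrec("TP53", "rs2", "p.Gly10Arg")]
        matrix = substitution_matrix(records, gene_filter={"COL1A1"}.__contains__)
        assert matrix.total == 1

    def test_total_invariant_under_shuffle(self, tiny_dataset):
        records, _ = data_io.read_variant_table(tiny_dataset.variants)
        forward = substitution_matrix(records)
        backward = substitution_matrix(list(reversed(records)))
        assert (forward.counts == backward.counts).all()

    def test_planted_distribution_recovered(self, tiny_dataset):
        records, _ = data_io.read_variant_table(tiny_dataset.variants)
        matrix = substitution_matrix(records)
        planted = tiny_dataset.manifest["variants"]["substitution_counts"]
        observed = {f"{r}>{a}": int(c) for r, a, c in
                    matrix.to_long().itertuples(index=False)}
        assert observed == planted


class TestRanking:
    def test_descending_order(self):
        records = ([vrec("G", f"r{i}", "p.Gly1Arg") for i in range(10)]
                   + [vrec("G", f"p{i}", "p.Pro1Leu") for i in range(4)]
                   + [vrec("G", f"a{i}", "p.Arg1Cys") for i in range(3)])
        top = [code for code, _ in rank_substituted(substitution_matrix(records))[:3]]
        assert top == ["Gly", "Pro", "Arg"]

    def test_all_zero_ties_alphabetical(self):
        ranking = rank_substituted(substitution_matrix([]))
        codes = [code for code, _ in ranking]
        assert codes == sorted(codes)

    def test_rank_targets(self):
        records = ([vrec("G", f"r{i}", "p.Gly1Arg") for i in range(5)]
                   + [vrec("G", f"d{i}", "p.Gly1Asp") for i in range(3)]
                   + [vrec("G", f"s{i}", "p.Gly1Ser") for i in range(2)])
        top = [code for code, count in rank_targets(substitution_matrix(records), "Gly") if count]
        assert top == ["Arg", "Asp", "Ser"]


class TestTripletPosition:
    def test_start_is_slot_one(self):
        slot = triplet_position(1, helix_start=1, offset=0)
        assert slot.position_in_triplet == 1 and slot.is_glycine_slot

    def test_periodicity(self):
        for p in range(5, 40):
            assert (triplet_position(p).position_in_triplet
                    == triplet_position(p + 3).position_in_triplet)

    def test_glycine_slots_brute_force(self):
        # slot 1, helix start 1: positions 1, 4, 7, ... are glycine slots
        expected = {p for p in range(1, 31) if (p - 1) % 3 == 0}
        flagged = {p for p in range(1, 31) if triplet_position(p).is_glycine_slot}
        assert flagged == expected

    def test_position_before_helix_start_raises(self):
        with pytest.raises(ValueError):
            triplet_position(3, helix_start=10)

    def test_configurable_glycine_slot(self):
        slot = triplet_position(3, helix_start=1, glycine_slot=3)
        assert slot.position_in_triplet == 3 and slot.is_glycine_slot


class TestVariantsPerDisease:
    def test_shared_variant_id_counts_once(self):
        records = [vrec("G", "rs1", None, "d1"), vrec("G", "rs1", None, "d1"),
                   vrec("G", "rs2", None, "d2")]
        table = variants_per_disease(records)
        assert dict(zip(table.disease, table.n_variants)) == {"d1": 1, "d2": 1}

    def test_empty_input(self):
        assert variants_per_disease([]).empty

    def test_planted_top_disease_first(self, tiny_dataset):
        records, _ = data_io.read_variant_table(tiny_dataset.variants)
        catalog, _ = data_io.read_matrisome_list(tiny_dataset.matrisome)
        matrisome = [r for r in records if r.gene_symbol in catalog]
        table = variants_per_disease(matrisome)
        planted = tiny_dataset.manifest["variants"]["per_disease_unique_variants"]
        top = max(planted, key=lambda d: (planted[d], d))
        assert table.iloc[0].n_variants == planted[top]
        assert dict(zip(table.disease, table.n_variants)) == planted
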