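"""Conserved-element search, dot notation and variant tables."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocr.elements import (
    DEFAULT_MAX_MISMATCHES,
    REFERENCE_MOTIFS,
    TAS2_UPDATED,
    VariantTable,
    annotate_elements,
    assign_variant_type,
    expand_dots,
    fuzzy_find,
    load_variant_table,
    parse_variant_table,
    render_dots,
    tabulate_variant_counts,
)

from conftest import window_scan_oracle

ELEMENTS = ("TAS1", "TAS2", "CSB1", "CSB2", "CSB3")


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFuzzyFind:
    def test_exact_tas2(self):
        seq = "G" * 30 + REFERENCE_MOTIFS["TAS2"] + "G" * 30
        hits = fuzzy_find(seq, "TAS2", 2)
        assert hits[0].start == 30 and hits[0].mismatch_count == 0
        assert hits[0].best

    def test_updated_tas2_anchor_mismatch_pattern(self):
        seq = "G" * 20 + TAS2_UPDATED + "G" * 20
        hits = fuzzy_find(seq, "TAS2", 2)
        # classic reference CATACATTAA vs TATGCATTAA: 0-based positions 0 and 3
        assert [(p, r, o) for p, r, o in hits[0].mismatch_positions] == [
            (0, "C", "T"),
            (3, "A", "G"),
        ]
        assert hits[0].dot_pattern == "T··G······"

    def test_matches_exhaustive_window_oracle(self):
        rng = random.Random(12)
        ref = REFERENCE_MOTIFS["CSB1"]
        base = _random_dna(rng, 400)
        mutated = list(ref)
        for pos in rng.sample(range(len(ref)), 3):
            mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
        seq = base[:180] + "".join(mutated) + base[180:]
        for max_mm in (3, 6, 9):
            hits = fuzzy_find(seq, "CSB1", max_mm)
            expect = sorted(window_scan_oracle(seq, ref, max_mm), key=lambda t: (t[1], t[0]))
            assert [(h.start, h.mismatch_count) for h in hits] == expect
        best = fuzzy_find(seq, "CSB1", 3)[0]
        assert (best.start, best.mismatch_count) == (180, 3)

    def test_sorted_by_mismatch_then_start(self):
        ref = REFERENCE_MOTIFS["TAS2"]
        seq = "T" + ref[1:] + "AAAA" + ref  # 1-mismatch hit before exact hit
        hits = fuzzy_find(seq, "TAS2", 2)
        assert hits[0].mismatch_count == 0 and hits[0].start == len(ref) + 4

    def test_no_hits_on_clean_random_sequence(self):
        rng = random.Random(99)
        assert fuzzy_find(_random_dna(rng, 100), "CSB1", 2) == []

    def test_ordered_annotation_restricts_downstream(self):
        # TAS2 planted before TAS1: ordered search must not report it
        seq = (
            "G" * 10 + REFERENCE_MOTIFS["TAS2"] + "G" * 10
            + REFERENCE_MOTIFS["TAS1"] + "G" * 10
        )
        ordered = annotate_elements(seq, ordered=True)
        assert "TAS2" not in ordered
        unordered = annotate_elements(seq, ordered=False)
        assert unordered["TAS2"].start == 10


class TestDotNotation:
    def test_identity_renders_all_dots(self):
        ref = REFERENCE_MOTIFS["CSB2"]
        assert render_dots(ref, ref) == "·" * len(ref)

    def test_printed_variant_pattern(self):
        assert render_dots(TAS2_UPDATED, REFERENCE_MOTIFS["TAS2"]) == "T··G······"

    @settings(derandomize=True, max_examples=80)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=40), st.randoms())
    def test_expand_inverts_render(self, ref, rnd):
        observed = "".join(
            rnd.choice("ACGT") if rnd.random() < 0.3 else b for b in ref
        )
        assert expand_dots(render_dots(observed, ref), ref) == observed

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            render_dots("ACG", "ACGT")


class TestVariantTables:
    @pytest.mark.parametrize(
        "element, n_rows", [("TAS1", 9), ("TAS2", 26), ("CSB1", 18), ("CSB2", 6), ("CSB3", 8)]
    )
    def test_shipped_tables_load(self, element, n_rows):
        t = load_variant_table(element)
        assert len(t.rows) == n_rows
        assert t.reference == REFERENCE_MOTIFS[element]
        for _, motif, _ in t.rows:
            assert len(motif) == len(t.reference)

    def test_single_all_dots_row(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text(
            "# element=TAS2\n# reference=CATACATTAA\n"
            "type_id\tdot_pattern\tspecies\n1\t··········\tX. species\n"
        )
        t = parse_variant_table(p)
        assert t.rows == [(1, "CATACATTAA", ("X. species",))]

    def test_bad_row_width_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "# element=TAS2\n# reference=CATACATTAA\n"
            "type_id\tdot_pattern\tspecies\n7\t·····\tY. sp\n"
        )
        with pytest.raises(ValueError, match="7"):
            parse_variant_table(p)

    @pytest.mark.parametrize("element", ELEMENTS)
    def test_rerendering_reproduces_fixture_dots(self, element):
        t = load_variant_table(element)
        import csv
        from importlib import resources
        from mitocr.elements import _TABLE_FILES

        raw_rows = {}
        with resources.files("mitocr.data").joinpath(_TABLE_FILES[element]).open() as fh:
            for row in csv.reader((l for l in fh if not l.startswith("#")), delimiter="\t"):
                if row and row[0] != "type_id":
                    raw_rows[int(row[0])] = row[1]
        for type_id, motif, _ in t.rows:
            assert render_dots(motif, t.reference) == raw_rows[type_id]

    @pytest.mark.parametrize("element", ELEMENTS)
    def test_classifying_rows_is_self_consistent(self, element):
        t = load_variant_table(element)
        expanded = t.expanded()
        for type_id, motif, _ in t.rows:
            hit = fuzzy_find("GG" + motif + "GG", element, len(motif))[0]
            got = assign_variant_type(hit, t)
            # duplicate-motif rows resolve to the first matching type id
            assert expanded[got] == motif

    def test_novel_motif(self):
        t = load_variant_table("CSB2")
        ref = t.reference
        weird = "G" * len(ref)
        hit = fuzzy_find(weird + "AA", "CSB2", len(ref))[0]
        assert assign_variant_type(hit, t) == "novel"

    def test_default_budget_flags_most_degenerate_csb3_as_novel(self):
        t = load_variant_table("CSB3")
        motif = t.expanded()[8]  # most degenerate published CSB3 variant
        assert fuzzy_find("GG" + motif + "GG", "CSB3") == []  # default budget
        hits = fuzzy_find("GG" + motif + "GG", "CSB3", 8)
        assert assign_variant_type(hits[0], t) == 8

    def test_element_table_mismatch_errors(self):
        t = load_variant_table("TAS2")
        hit = fuzzy_find("GG" + REFERENCE_MOTIFS["CSB2"] + "GG", "CSB2", 0)[0]
        with pytest.raises(ValueError):
            assign_variant_type(hit, t)


class TestTabulation:
    def test_reference_motif_counts(self):
        t4 = load_variant_table("CSB1")
        assert tabulate_variant_counts(t4, lambda m: m == t4.reference) == 12

    def test_first_base_predicate(self):
        t6 = load_variant_table("TAS2")
        assert tabulate_variant_counts(t6, lambda m: m[0] == "T") == 29

    def test_empty_table(self):
        t = VariantTable(element="TAS2", reference=REFERENCE_MOTIFS["TAS2"], rows=[])
        assert tabulate_variant_counts(t, lambda m: True) == 0
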