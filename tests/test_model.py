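"""Genome model: I/O round trips, CR extraction, overlap and OL scanning."""

import random

import pytest

from mitocr.model import (
    CANONICAL_GENE_ORDER,
    OL_MOTIF_25,
    OL_MOTIF_26,
    GenBankParseError,
    GeneFeature,
    MitogenomeRecord,
    classify_overlap_motif,
    extract_control_region,
    levenshtein,
    read_genbank,
    resolve_gene_name,
    scan_gene_overlaps,
    scan_ol_motif,
    write_genbank,
)


def _record(length, features, circular=True, seed=0):
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    return MitogenomeRecord("t1", seq, circular=circular, features=features)


class TestNameResolution:
    @pytest.mark.parametrize(
        "alias, canonical",
        [
            ("COX1", "COI"),
            ("COX3", "COIII"),
            ("cytochrome b", "CYTB"),
            ("CYTB", "CYTB"),
            ("D-loop", "CR"),
            ("tRNA-Phe", "trnF"),
            ("tRNA-Ser(AGN)", "trnS1"),
            ("tRNA-Leu(UUR)", "trnL2"),
            ("12S ribosomal RNA", "rrnS"),
            ("NAD4L", "ND4L"),
        ],
    )
    def test_synonyms_resolve(self, alias, canonical):
        assert resolve_gene_name(alias) == canonical

    def test_unknown_label_unresolved(self):
        assert resolve_gene_name("totally-novel-orf") is None


class TestGenBankIO:
    def test_round_trip_preserves_features(self, default_genome, tmp_path):
        record, _ = default_genome
        path = tmp_path / "genome.gb"
        write_genbank([record], path)
        back = read_genbank(path)[0]
        assert back.sequence == record.sequence
        assert back.circular
        assert [(f.name, f.start, f.end, f.strand, f.wraps_origin) for f in back.features] == [
            (f.name, f.start, f.end, f.strand, f.wraps_origin) for f in record.features
        ]

    def test_wrapping_feature_round_trip(self, tmp_path):
        feats = [
            GeneFeature("trnP", "L", 150, 220),
            GeneFeature("CR", "H", 220, 40, wraps_origin=True),
            GeneFeature("trnF", "H", 40, 110),
        ]
        rec = _record(300, feats)
        path = tmp_path / "wrap.gb"
        write_genbank([rec], path)
        back = read_genbank(path)[0]
        cr = back.feature("CR")
        assert (cr.start, cr.end, cr.wraps_origin) == (220, 40, True)

    def test_missing_file_content_errors(self, tmp_path):
        p = tmp_path / "empty.gb"
        p.write_text("")
        with pytest.raises(GenBankParseError):
            read_genbank(p)


class TestControlRegionExtraction:
    def test_simple_interval(self):
        rec = _record(
            18000,
            [GeneFeature("trnP", "L", 14930, 15000), GeneFeature("trnF", "H", 16200, 16270)],
        )
        cr = extract_control_region(rec)
        assert (cr.start, cr.end, cr.length, cr.wraps_origin) == (15000, 16200, 1200, False)

    def test_wrapping_interval_modular_arithmetic(self):
        rec = _record(
            18000,
            [GeneFeature("trnP", "L", 17830, 17900), GeneFeature("trnF", "H", 100, 170)],
        )
        cr = extract_control_region(rec)
        assert (cr.length, cr.wraps_origin) == (200, True)
        # oracle: concatenation across the origin
        assert cr.sequence == rec.sequence[17900:] + rec.sequence[:100]

    def test_missing_boundary_trna_names_culprit(self):
        rec = _record(1000, [GeneFeature("trnP", "L", 10, 80)])
        with pytest.raises(ValueError, match="tRNA-Phe"):
            extract_control_region(rec)

    def test_generator_round_trip_length(self, default_genome):
        record, gt = default_genome
        cr = extract_control_region(record)
        assert (cr.start, cr.start + cr.length) == gt.cr_interval
        assert cr.length == gt.cr.length


class TestOverlapScanner:
    def test_atp8_atp6_motif_overlap(self, default_genome):
        record, _ = default_genome
        ovs = {(o.gene_a, o.gene_b): o for o in scan_gene_overlaps(record)}
        atp = ovs[("ATP8", "ATP6")]
        assert atp.overlap_length == 10
        assert atp.motif_class == "ATGGNNNTAA"

    def test_configured_overlap_lengths(self, default_genome):
        record, gt = default_genome
        got = {
            (o.gene_a, o.gene_b): o.overlap_length for o in scan_gene_overlaps(record)
        }
        assert got == {
            ("ATP8", "ATP6"): 10,
            ("ATP6", "COIII"): 1,
            ("ND4L", "ND4"): 7,
            ("ND5", "ND6"): 5,
        }

    def test_adjacent_genes_do_not_overlap(self):
        rec = _record(
            500,
            [GeneFeature("trnF", "H", 0, 70), GeneFeature("rrnS", "H", 70, 400)],
        )
        assert scan_gene_overlaps(rec) == []

    def test_matches_interval_intersection_oracle(self):
        rng = random.Random(42)
        names = [g for g, _ in CANONICAL_GENE_ORDER if g not in ("CR", "OL")]
        for trial in range(20):
            n = 5000
            feats = []
            chosen = rng.sample(names, rng.randint(2, 30))
            for name in chosen:
                start = rng.randrange(0, n - 200)
                feats.append(
                    GeneFeature(name, "H", start, start + rng.randint(30, 180))
                )
            feats.sort(key=lambda f: f.start)
            rec = MitogenomeRecord("r", "A" * n, features=feats)
            got = {
                frozenset((o.gene_a, o.gene_b)): o.overlap_length
                for o in scan_gene_overlaps(rec)
            }
            expect = {}
            for i, a in enumerate(feats):
                for b in feats[i + 1 :]:
                    lo, hi = max(a.start, b.start), min(a.end, b.end)
                    if hi > lo:
                        expect[frozenset((a.name, b.name))] = hi - lo
            assert got == expect

    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ATGGCCCTAA", "ATGGNNNTAA"),
            ("ATGACTAA", "ATGANTAA"),
            ("ATGTTTTAA", "none"),
            ("AT", "none"),
        ],
    )
    def test_motif_classification(self, seq, expected):
        assert classify_overlap_motif(seq) == expected


class TestOLMotif:
    def test_embedded_instantiation_found(self):
        core = "TTCCCCCGTTAGACTGAAAACGGGGG"  # 26 nt pattern, N's instantiated
        rec = _record(400, [], seed=5)
        seq = rec.sequence[:100] + core + rec.sequence[100 + len(core):]
        rec2 = MitogenomeRecord("t", seq, features=[])
        hits = scan_ol_motif(rec2)
        assert [(h.start, h.pattern_length, h.matched_motif) for h in hits] == [
            (100, 26, OL_MOTIF_26)
        ]

    def test_random_sequence_has_no_hits(self):
        rec = _record(5000, [], seed=9)
        assert scan_ol_motif(rec) == []

    def test_generator_motif_recovered(self, default_genome):
        record, gt = default_genome
        hits = scan_ol_motif(record)
        assert any(h.start == gt.ol_motif_start for h in hits)

    def test_printed_patterns_differ_by_one_edit(self):
        assert levenshtein(OL_MOTIF_26, OL_MOTIF_25) == 1

    def test_match_across_origin_on_circular_record(self):
        core = "TTCCCCCGTTAGACTGAAAACGGGGG"
        base = _record(300, [], seed=3).sequence
        seq = core[10:] + base[:274] + core[:10]
        rec = MitogenomeRecord("c", seq, circular=True, features=[])
        assert any(h.start == len(seq) - 10 for h in scan_ol_motif(rec))
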