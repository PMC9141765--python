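"""Synthetic-data generators: determinism, ground-truth round trips."""

import pytest

from mitocr.crtypes import annotate_cr_sequence, classify_cr
from mitocr.elements import fuzzy_find
from mitocr.model import extract_control_region, read_genbank, scan_ol_motif, write_genbank
from mitocr.repeats import find_tandem_repeats
from mitocr.synth import (
    CR_PRESETS,
    CRSpec,
    SyntheticSpec,
    TRArraySpec,
    cr_spec_for_subtype,
    generate_cr,
    generate_mitogenome,
    simulate_codon_alignment,
)


class TestDeterminism:
    def test_cr_generation_reproducible(self):
        a, gta = generate_cr(CR_PRESETS["eremias_typical"], seed=17)
        b, gtb = generate_cr(CR_PRESETS["eremias_typical"], seed=17)
        assert a == b and gta == gtb
        c, _ = generate_cr(CR_PRESETS["eremias_typical"], seed=18)
        assert c != a

    def test_mitogenome_reproducible(self):
        r1, _ = generate_mitogenome(SyntheticSpec(), seed=4)
        r2, _ = generate_mitogenome(SyntheticSpec(), seed=4)
        assert r1.sequence == r2.sequence

    def test_alignment_simulation_reproducible(self):
        a1, t1 = simulate_codon_alignment(3, 100, 0.05, 0.02, seed=9)
        a2, t2 = simulate_codon_alignment(3, 100, 0.05, 0.02, seed=9)
        assert a1 == a2 and t1 == t2


class TestCRRoundTrips:
    @pytest.mark.parametrize("preset", sorted(CR_PRESETS))
    def test_annotation_recovers_ground_truth(self, preset):
        seq, gt = generate_cr(CR_PRESETS[preset], seed=1)
        hits, trs, _ = annotate_cr_sequence(seq, preset)
        assert set(hits) == set(gt.elements)
        for element, (start, end, motif) in gt.elements.items():
            h = hits[element]
            assert (h.start, h.end, h.matched_sequence) == (start, end, motif)
        for t in gt.trs:
            assert any(
                (h.start, h.end, h.period) == (t["start"], t["end"], t["period"])
                and h.position_class == t["position_class"]
                for h in trs
            ), f"{preset}: TR {t} not recovered exactly"

    def test_presets_classify_to_intended_subtypes(self, rules):
        expected = {
            "eremias_typical": "I-4",
            "darevskia_typical": "II-1",
            "takydromus_typical": "III-1",
            "minimal_V": "V-1",
        }
        for preset, subtype in expected.items():
            seq, _ = generate_cr(CR_PRESETS[preset], seed=1)
            _, _, profile = annotate_cr_sequence(seq, preset)
            assert classify_cr(profile, rules).subtype == subtype

    def test_every_rule_has_a_realizable_cr(self, rules):
        """Generator <-> classifier consistency over all 21 subtypes."""
        for rule in rules:
            spec = cr_spec_for_subtype(rule)
            seq, _ = generate_cr(spec, seed=7)
            _, _, profile = annotate_cr_sequence(
                seq, rule.label, ordered=(rule.order_ok is not False)
            )
            assert classify_cr(profile, rules).subtype == rule.label

    def test_variant_pattern_embedded_and_reported(self):
        spec = CRSpec(elements=(("TAS2", "T··G······"),), trs=())
        seq, gt = generate_cr(spec, seed=2)
        hit = fuzzy_find(seq, "TAS2", 2)[0]
        assert [p for p, _, _ in hit.mismatch_positions] == [0, 3]
        assert (hit.start, hit.end) == gt.elements["TAS2"][:2]

    def test_zero_tr_spec_detects_nothing(self):
        seq, gt = generate_cr(CR_PRESETS["minimal_V"], seed=3)
        assert gt.trs == []
        assert find_tandem_repeats(seq) == []

    def test_csb2_csb3_gap_is_35(self):
        seq, gt = generate_cr(CR_PRESETS["eremias_typical"], seed=1)
        assert gt.elements["CSB3"][0] - gt.elements["CSB2"][1] == 35

    def test_unplaceable_tr_class_errors(self):
        spec = CRSpec(
            elements=(("CSB2", None), ("CSB3", None)),
            trs=(TRArraySpec("before_TAS1", "GCGGCTT", 3),),
        )
        with pytest.raises(ValueError, match="position class"):
            generate_cr(spec, seed=1)

    def test_spacer_composition_tracks_target(self):
        spec = CRSpec(elements=(("CSB3", None),), trs=(), lead=1500, tail=40,
                      at_percent=62.0)
        seq, gt = generate_cr(spec, seed=5)
        lead = seq[: gt.elements["CSB3"][0]]
        assert len(lead) >= 1000
        at = 100.0 * sum(1 for b in lead if b in "AT") / len(lead)
        assert abs(at - 62.0) <= 2.0


class TestMitogenome:
    def test_feature_table_is_complete(self, default_genome):
        record, gt = default_genome
        assert len(record.features) == 39  # 37 genes + OL + CR
        names = [f.name for f in record.features]
        assert names.count("CR") == 1 and names.count("OL") == 1

    def test_configured_overlaps_reported(self, default_genome):
        from mitocr.model import scan_gene_overlaps

        record, gt = default_genome
        got = {f"{o.gene_a}|{o.gene_b}": o.overlap_length for o in scan_gene_overlaps(record)}
        assert got == gt.overlaps

    def test_no_ol_motif_when_disabled(self):
        record, _ = generate_mitogenome(
            SyntheticSpec(include_ol_motif=False), seed=6
        )
        assert scan_ol_motif(record) == []

    def test_cr_matches_embedded_ground_truth(self, default_genome):
        record, gt = default_genome
        cr = extract_control_region(record)
        assert cr.length == gt.cr.length
        offset = gt.cr_interval[0]
        for element, (s, e, motif) in gt.cr.elements.items():
            assert record.sequence[offset + s : offset + e] == motif

    def test_genome_length_target_pads_cr(self):
        spec = SyntheticSpec(genome_length=18000)
        record, gt = generate_mitogenome(spec, seed=2)
        assert len(record) == 18000
        assert gt.cr_interval[1] - gt.cr_interval[0] == extract_control_region(record).length

    def test_infeasible_genome_length_errors(self):
        with pytest.raises(ValueError):
            generate_mitogenome(SyntheticSpec(genome_length=10000), seed=1)

    def test_genbank_round_trip_of_generator_output(self, default_genome, tmp_path):
        record, _ = default_genome
        write_genbank([record], tmp_path / "syn.gb")
        back = read_genbank(tmp_path / "syn.gb")[0]
        assert [(f.name, f.start, f.end) for f in back.features] == [
            (f.name, f.start, f.end) for f in record.features
        ]

    def test_pcg_start_and_stop_codons(self, default_genome):
        record, _ = default_genome
        for gene, start_codons in (("ND2", {"ATG"}), ("COI", {"GTG"}), ("CYTB", {"ATG"})):
            cds = record.feature_seq(gene)
            assert cds[:3] in start_codons
            assert cds[-3:] in {"TAA", "TAG", "AGG", "AGA"}


class TestAlignmentSimulation:
    def test_rates_validate(self):
        with pytest.raises(ValueError):
            simulate_codon_alignment(2, 10, -0.1, 0.1, seed=1)
        with pytest.raises(ValueError):
            simulate_codon_alignment(0, 10, 0.1, 0.1, seed=1)

    def test_no_stop_codons_ever_created(self):
        aln, _ = simulate_codon_alignment(5, 200, 0.2, 0.2, seed=12)
        from mitocr.composition import STOP_CODONS

        for _, seq in aln:
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & STOP_CODONS

    def test_equal_rates_give_balanced_proportions(self):
        """pN/pS ~ 1 when synonymous and nonsynonymous changes are accepted
        at the same rate (uniform proposals make pS and pN estimate the same
        per-site substitution probability)."""
        from mitocr.dnds import ng86_pair

        aln, _ = simulate_codon_alignment(2, 2000, 0.15, 0.15, seed=21)
        (_, a), (_, b) = aln
        r = ng86_pair(a, b)
        assert r.ps > 0 and r.pn > 0
        # 3 Monte-Carlo standard errors of the ratio at this divergence
        assert r.pn / r.ps == pytest.approx(1.0, abs=0.35)
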