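"""Splice-pattern, reading-frame, boundary and mechanism classification."""

import random

import pytest

from gfml.fusion_semantics import (
    ExonModel,
    FrameInput,
    classify_boundary,
    classify_fusion_product,
    classify_splice_pattern,
    compute_orf_status,
    infer_mechanism,
)
from gfml.model import FusionPartner, GfmlError

from oracles import boundary_by_scan, frame_status_by_translation, random_junction


class TestSplicePattern:
    def test_gt_ag_is_canonical(self):
        assert classify_splice_pattern("GT", "AG") == "canonical"
        assert classify_splice_pattern("gt", "ag") == "canonical"

    def test_minor_spliceosome_pairs_are_non_canonical(self):
        assert classify_splice_pattern("GC", "AG") == "non_canonical"
        assert classify_splice_pattern("AT", "AC") == "non_canonical"

    def test_exhaustive_16x16_table_has_exactly_one_canonical_cell(self):
        bases = "ACGT"
        pairs = [
            (a + b, c + d) for a in bases for b in bases for c in bases for d in bases
        ]
        assert len(pairs) == 256
        canonical = [
            p for p in pairs if classify_splice_pattern(*p) == "canonical"
        ]
        assert canonical == [("GT", "AG")]

    @pytest.mark.parametrize("bad", ["G", "GTT", "NX", "", "G-"])
    def test_malformed_dinucleotide_is_an_error(self, bad):
        with pytest.raises(GfmlError):
            classify_splice_pattern(bad, "AG")


class TestOrfStatus:
    @pytest.mark.parametrize(
        "coding_len, phase, expected",
        [
            (300, 0, "in_frame"),
            (301, 0, "out_of_frame"),
            (100, 1, "in_frame"),  # 100 mod 3 = 1
            (100, 2, "out_of_frame"),
        ],
    )
    def test_frame_rule_on_known_lengths(self, coding_len, phase, expected):
        assert (
            compute_orf_status(FrameInput(coding_len_5p=coding_len, phase_3p=phase))
            == expected
        )

    def test_degenerate_cases(self):
        assert compute_orf_status(FrameInput(coding_len_5p=0)) == "promoter_swap"
        assert (
            compute_orf_status(FrameInput(coding_len_5p=10, three_prime_coding=False))
            == "non_coding"
        )
        assert compute_orf_status(FrameInput(coding_len_5p=None)) == "unknown"
        assert compute_orf_status(FrameInput(coding_len_5p=9, phase_3p=None)) == "unknown"

    def test_invalid_phase_rejected(self):
        with pytest.raises(GfmlError):
            FrameInput(coding_len_5p=3, phase_3p=3)

    def test_agrees_with_translation_oracle_on_randomized_junctions(self):
        """Build toy CDS pairs, join them at the junction, translate, and
        ask whether the 3' peptide survives; the frame rule must agree."""
        rng = random.Random(2024)
        for _ in range(500):
            retained_5p, cds3, cut = random_junction(rng)
            expected = frame_status_by_translation(retained_5p, cds3, cut)
            computed = compute_orf_status(
                FrameInput(coding_len_5p=len(retained_5p), phase_3p=cut % 3)
            )
            assert computed == expected


class TestFusionProduct:
    @pytest.mark.parametrize(
        "orf, product",
        [
            ("in_frame", "fusion_protein"),
            ("out_of_frame", "truncated_protein"),
            ("promoter_swap", "promoter_swap"),
            ("non_coding", "non_coding"),
            ("unknown", "unknown"),
        ],
    )
    def test_orf_to_product_mapping(self, orf, product):
        assert classify_fusion_product(orf) == product


class TestBoundary:
    EXONS = ExonModel(exons=[(100, 200), (300, 400), (500, 600)])

    @pytest.mark.parametrize(
        "breakpoint, expected",
        [
            (400, "exon_boundary"),  # exon 2 end
            (300, "exon_boundary"),
            (350, "within_exon"),
            (250, "intronic"),
            (50, "intergenic"),
            (601, "intergenic"),
        ],
    )
    def test_known_positions(self, breakpoint, expected):
        assert classify_boundary(breakpoint, self.EXONS) == expected

    def test_empty_model_gives_unknown(self):
        assert classify_boundary(100, ExonModel(exons=[])) == "unknown"

    def test_random_breakpoints_match_interval_scan(self):
        rng = random.Random(7)
        for _ in range(1000):
            bp = rng.randint(1, 700)
            assert classify_boundary(bp, self.EXONS) == boundary_by_scan(
                bp, self.EXONS.exons, self.EXONS.gene_span
            )

    def test_partition_and_exon_order_invariance(self):
        classes = {"exon_boundary", "within_exon", "intronic", "intergenic"}
        permuted = ExonModel(exons=[(500, 600), (100, 200), (300, 400)])
        for bp in range(1, 700, 13):
            cls = classify_boundary(bp, self.EXONS)
            assert cls in classes
            assert classify_boundary(bp, permuted) == cls

    def test_bed_loading_converts_to_one_based_closed(self, tmp_path):
        bed = tmp_path / "exons.bed"
        bed.write_text("chr1\t99\t200\t+\nchr1\t299\t400\t+\n")
        exons = ExonModel.from_bed(str(bed))
        assert exons.exons == [(100, 200), (300, 400)]


def _partner(role, chrom, strand, breakpoint):
    return FusionPartner(
        role=role, gene_symbol="X", chromosome=chrom, strand=strand, breakpoint=breakpoint
    )


class TestMechanism:
    def test_different_chromosomes_is_translocation(self):
        p5 = _partner("five_prime", "chr21", "+", 1000)
        p3 = _partner("three_prime", "chr10", "+", 2000)
        assert infer_mechanism(p5, p3) == "translocation"

    def test_same_chromosome_opposite_strands_is_inversion(self):
        p5 = _partner("five_prime", "chr7", "+", 1000)
        p3 = _partner("three_prime", "chr7", "-", 2000)
        assert infer_mechanism(p5, p3) == "inversion"

    def test_truth_table_of_same_chromosome_configurations(self):
        """All strand/order combinations on one chromosome."""
        far = 5_000_000  # beyond the read-through adjacency threshold
        near = 50_000
        cases = [
            # (strand5, strand3, bp5, bp3, expected)
            ("+", "+", 1_000_000, 1_000_000 + far, "deletion"),
            ("+", "+", 1_000_000, 1_000_000 + near, "read_through"),
            ("+", "+", 1_000_000 + far, 1_000_000, "tandem_duplication"),
            ("-", "-", 1_000_000 + far, 1_000_000, "deletion"),
            ("-", "-", 1_000_000 + near, 1_000_000, "read_through"),
            ("-", "-", 1_000_000, 1_000_000 + far, "tandem_duplication"),
            ("+", "-", 1_000_000, 2_000_000, "inversion"),
            ("-", "+", 2_000_000, 1_000_000, "inversion"),
        ]
        for strand5, strand3, bp5, bp3, expected in cases:
            p5 = _partner("five_prime", "chr3", strand5, bp5)
            p3 = _partner("three_prime", "chr3", strand3, bp3)
            assert infer_mechanism(p5, p3) == expected, (strand5, strand3, bp5, bp3)

    def test_missing_fields_give_unknown(self):
        p5 = _partner("five_prime", "", "+", 100)
        p3 = _partner("three_prime", "chr1", "+", 200)
        assert infer_mechanism(p5, p3) == "unknown"
        p5 = _partner("five_prime", "chr1", "?", 100)
        assert infer_mechanism(p5, p3) == "unknown"

    def test_chromosome_relabeling_invariance(self):
        rng = random.Random(11)
        for _ in range(100):
            c5, c3 = rng.choice(["chr1", "chr2"]), rng.choice(["chr1", "chr2"])
            s5, s3 = rng.choice("+-"), rng.choice("+-")
            b5, b3 = rng.randint(1, 10**7), rng.randint(1, 10**7)
            relabel = {"chr1": "chr9", "chr2": "chr12"}
            before = infer_mechanism(
                _partner("five_prime", c5, s5, b5), _partner("three_prime", c3, s3, b3)
            )
            after = infer_mechanism(
                _partner("five_prime", relabel[c5], s5, b5),
                _partner("three_prime", relabel[c3], s3, b3),
            )
            assert before == after
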