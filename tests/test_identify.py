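"""Class-code assignment, ORF scoring and the identification cascade."""

import numpy as np
import pytest

from cerna.identify import (
    IdentifyParams,
    assign_class_code,
    coding_potential_score,
    identify_lncrnas,
)
from cerna.models import GenomicInterval, TranscriptModel
from cerna.seq import random_dna

from oracles import (
    brute_force_class_code,
    exhaustive_longest_orf,
    random_transcript,
)


def tx(tid, chrom, strand, *exon_coords, seq=None, reads=0):
    return TranscriptModel(
        id=tid,
        exons=tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in exon_coords
        ),
        sequence=seq,
        read_support=reads,
    )


REF = tx("ref", "chr1", "+", (100, 400), (600, 1000), (1300, 1600))


class TestClassCode:
    def test_single_exon_inside_intron_is_i(self):
        cand = tx("c", "chr1", "+", (450, 550))
        assert assign_class_code(cand, [REF]) == "i"

    def test_identical_transcript_is_equal(self):
        cand = tx("c", "chr1", "+", (100, 400), (600, 1000), (1300, 1600))
        assert assign_class_code(cand, [REF]) == "="

    def test_shared_junction_is_j(self):
        cand = tx("c", "chr1", "+", (200, 400), (600, 800))
        assert assign_class_code(cand, [REF]) == "j"

    def test_same_strand_exon_overlap_is_o(self):
        cand = tx("c", "chr1", "+", (300, 500))
        assert assign_class_code(cand, [REF]) == "o"

    def test_opposite_strand_overlap_is_x(self):
        cand = tx("c", "chr1", "-", (300, 500))
        assert assign_class_code(cand, [REF]) == "x"

    def test_intergenic_is_u(self):
        cand = tx("c", "chr1", "+", (5000, 5400))
        assert assign_class_code(cand, [REF]) == "u"

    def test_unknown_chromosome_is_u(self, caplog):
        cand = tx("c", "chr9", "+", (100, 400))
        assert assign_class_code(cand, [REF]) == "u"

    def test_strand_flip_swaps_o_and_x(self):
        plus = tx("c", "chr1", "+", (300, 500))
        minus = tx("c", "chr1", "-", (300, 500))
        assert assign_class_code(plus, [REF]) == "o"
        assert assign_class_code(minus, [REF]) == "x"
        flipped_ref = tx("r", "chr1", "-", (100, 400), (600, 1000))
        assert assign_class_code(plus, [flipped_ref]) == "x"
        assert assign_class_code(minus, [flipped_ref]) == "o"

    def test_matches_brute_force_on_random_cohort(self, rng):
        refs = [random_transcript(rng, f"r{i}") for i in range(20)]
        for i in range(200):
            cand = random_transcript(rng, f"c{i}")
            assert assign_class_code(cand, refs) == brute_force_class_code(
                cand, refs
            ), f"disagreement on {cand}"

    def test_annotation_order_never_matters(self, rng):
        refs = [random_transcript(rng, f"r{i}") for i in range(10)]
        for i in range(30):
            cand = random_transcript(rng, f"c{i}")
            codes = {
                assign_class_code(cand, list(perm))
                for perm in (
                    refs,
                    refs[::-1],
                    sorted(refs, key=lambda r: r.id, reverse=True),
                )
            }
            assert len(codes) == 1


class TestCodingPotential:
    def test_no_atg_is_noncoding(self):
        cp = coding_potential_score("CCCGGGCCC")
        assert cp.longest_orf_nt == 0 and cp.score == 0 and not cp.is_coding

    def test_full_length_orf_is_coding(self):
        # 300 nt = ATG + 98 sense codons + stop: one ORF spanning everything
        seq = "ATG" + "GGC" * 98 + "TAA"
        cp = coding_potential_score(seq)
        assert len(seq) == 300
        assert cp.longest_orf_nt == 300 and cp.score == 1.0 and cp.is_coding

    def test_orf_without_stop_does_not_count(self):
        cp = coding_potential_score("ATG" + "GGC" * 50)
        assert cp.longest_orf_nt == 0

    def test_invalid_character_named(self):
        with pytest.raises(ValueError, match="position 2"):
            coding_potential_score("ACNTG")

    def test_matches_exhaustive_scanner(self, rng):
        for _ in range(40):
            seq = random_dna(rng, 1000)
            assert (
                coding_potential_score(seq).longest_orf_nt
                == exhaustive_longest_orf(seq)
            )


def noncoding_seq(n):
    # no ATG anywhere: ORF-free by construction
    return ("CCG" * (n // 3 + 1))[:n]


class TestCascade:
    def make_candidates(self):
        return [
            tx("short", "chr1", "+", (5000, 5150), seq=noncoding_seq(150), reads=5),
            tx("weak", "chr1", "+", (6000, 6300), seq=noncoding_seq(300), reads=2),
            tx(
                "coding",
                "chr1",
                "+",
                (7000, 7300),
                seq="ATG" + "GGC" * 98 + "TAA",
                reads=5,
            ),
            tx("good", "chr1", "+", (8000, 8400), seq=noncoding_seq(400), reads=5),
            tx(
                "known",
                "chr1",
                "+",
                (100, 400),
                (600, 1000),
                (1300, 1600),
                seq=noncoding_seq(1000),
                reads=5,
            ),
        ]

    def test_rejection_stages(self):
        retained, reports, table = identify_lncrnas(
            self.make_candidates(), [REF]
        )
        stages = dict(zip(table.transcript_id, table.rejection_stage))
        assert stages == {
            "short": "length",
            "weak": "read_support",
            "coding": "coding_potential",
            "good": "",
            "known": "known_mrna",
        }
        assert [t.id for t in retained] == ["good"]
        assert [r.stage for r in reports] == [
            "known_mrna",
            "length",
            "read_support",
            "coding_potential",
        ]
        for r in reports:
            assert r.retained_count + len(r.rejected) == r.input_count

    def test_empty_candidate_set(self):
        retained, reports, table = identify_lncrnas([], [REF])
        assert retained == [] and len(table) == 0
        assert all(r.input_count == 0 for r in reports)

    def test_tightening_thresholds_never_grows_retained(self, rng):
        cands = self.make_candidates()
        base, *_ = identify_lncrnas(cands, [REF], IdentifyParams())
        for params in (
            IdentifyParams(min_length=300),
            IdentifyParams(min_reads=6),
            IdentifyParams(orf_min_nt=100),
            IdentifyParams(orf_max_fraction=0.1),
        ):
            tighter, *_ = identify_lncrnas(cands, [REF], params)
            assert {t.id for t in tighter} <= {t.id for t in base}

    def test_recovers_planted_cohort(self, dataset):
        retained, _, table = identify_lncrnas(
            dataset.candidates + dataset.lncrnas, dataset.reference
        )
        codes = dict(zip(table.transcript_id, table.class_code))
        for tid, expected in dataset.truth.class_code_truth.items():
            assert codes[tid] == expected
        planted = {
            tid
            for tid, c in dataset.truth.class_code_truth.items()
            if c in "ijoux"
        } | {t.id for t in dataset.lncrnas}
        assert {t.id for t in retained} == planted
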