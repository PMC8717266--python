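import math

import pytest

from maexp.errors import CoordinateError
from maexp.genome import CDS, AnnotatedGenome
from maexp.model import MutationCall
from maexp.spectrum import (
    SubstitutionClass,
    TRANSITION,
    TRANSVERSION,
    classify_coding_effect,
    classify_substitution,
    count_spectrum,
    expected_ns_ratio,
    ns_ratio_test,
    partition_by_annotation,
    titv_ratio,
)

from .oracles import brute_force_ns_ratio

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def sub(pos, ref, alt, line="L1"):
    return MutationCall(line, pos, ref, alt, qual=1000, mq=60)


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,cls,kind",
        [
            ("G", "A", SubstitutionClass.GC_AT, TRANSITION),
            ("T", "C", SubstitutionClass.AT_GC, TRANSITION),
            ("G", "T", SubstitutionClass.GC_TA, TRANSVERSION),
            ("A", "T", SubstitutionClass.AT_TA, TRANSVERSION),
            ("C", "G", SubstitutionClass.GC_CG, TRANSVERSION),
            ("A", "C", SubstitutionClass.AT_CG, TRANSVERSION),
        ],
    )
    def test_collapsed_class_and_kind(self, ref, alt, cls, kind):
        got = classify_substitution(ref, alt)
        assert got is cls and got.kind == kind

    def test_strand_collapse_for_all_twelve_changes(self):
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert classify_substitution(ref, alt) is classify_substitution(
                    _COMP[ref], _COMP[alt]
                )

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")
        with pytest.raises(ValueError):
            classify_substitution("N", "A")


class TestTiTv:
    def test_study_counts(self):
        calls = [sub(i, "G", "A") for i in range(57)] + [sub(100 + i, "G", "T") for i in range(31)]
        assert titv_ratio(calls) == pytest.approx(57 / 31, abs=1e-9)
        assert round(titv_ratio(calls), 2) == 1.84

    def test_equal_counts(self):
        calls = [sub(0, "A", "G"), sub(1, "A", "T")]
        assert titv_ratio(calls) == 1.0

    def test_no_transitions(self):
        calls = [sub(i, "A", "T") for i in range(5)]
        assert titv_ratio(calls) == 0.0

    def test_no_transversions_flagged_as_infinite(self):
        assert math.isinf(titv_ratio([sub(0, "A", "G")]))

    def test_class_counts_sum_to_total(self):
        calls = [sub(i, r, a) for i, (r, a) in enumerate([("G", "A")] * 3 + [("A", "C")] * 2)]
        assert sum(count_spectrum(calls).values()) == len(calls)


class TestRegionPartition:
    def test_coding_label_follows_annotation(self):
        g = AnnotatedGenome("A" * 30 + "ATGAAATAA" + "A" * 30, [CDS(30, 39, "+")])
        calls = [sub(31, "T", "C"), sub(5, "A", "G"), sub(38, "A", "G")]
        part = partition_by_annotation(calls, g)
        assert part.n_coding == 2 and part.n_noncoding == 1

    def test_fully_coding_genome(self):
        g = AnnotatedGenome("ATGAAATAA", [CDS(0, 9, "+")])
        part = partition_by_annotation([sub(4, "A", "G")], g)
        assert part.n_noncoding == 0

    def test_balanced_toy_table_has_fisher_p_one(self):
        g = AnnotatedGenome("ATGAAATAA" + "T" * 9, [CDS(0, 9, "+")])
        calls = [sub(i, "A", "G") for i in (3, 4, 5, 7)] + [sub(i, "T", "C") for i in (10, 11, 12, 13)]
        part = partition_by_annotation(calls, g, denominator=2000.0)
        assert part.fisher_p == pytest.approx(1.0)

    def test_out_of_genome_position_rejected(self):
        g = AnnotatedGenome("ATGAAATAA", [CDS(0, 9, "+")])
        with pytest.raises(CoordinateError):
            partition_by_annotation([sub(99, "A", "G")], g)


class TestCodingEffect:
    def test_third_position_wobble_is_synonymous(self):
        g = AnnotatedGenome("ATGAAA", [CDS(0, 6, "+")])
        assert classify_coding_effect(sub(5, "A", "G"), g) == "synonymous"

    def test_first_position_change_is_nonsynonymous(self):
        g = AnnotatedGenome("ATGAAA", [CDS(0, 6, "+")])
        assert classify_coding_effect(sub(3, "A", "G"), g) == "nonsynonymous"

    def test_minus_strand_effect_matches_reverse_complement_logic(self):
        # minus-strand CDS: genome TTTCAT reads ATGAAA on the coding strand;
        # genome-forward G->A at position 3 is codon3 C->T (AAA->AAT? no:
        # here TTT|CAT revcomp = ATG|AAA; mutate genome pos 0 T->C =>
        # coding last base A->G: Lys AAA -> AAG Lys, synonymous.
        g = AnnotatedGenome("TTTCAT", [CDS(0, 6, "-")])
        assert classify_coding_effect(sub(0, "T", "C"), g) == "synonymous"
        # genome pos 5 T->C => coding first base A->G: AAA->GAA? coding
        # offset = end-1-5 = 0, codon ATG start... pos 5 is coding offset 0
        assert classify_coding_effect(sub(2, "T", "C"), g) == "nonsynonymous"

    def test_stop_gain_counts_as_nonsynonymous(self):
        g = AnnotatedGenome("ATGTGGTAA", [CDS(0, 9, "+")])  # Trp codon TGG
        assert classify_coding_effect(sub(5, "G", "A"), g) == "nonsynonymous"  # TGG->TGA stop

    def test_noncoding_position_rejected(self):
        g = AnnotatedGenome("ATGAAATAAGGG", [CDS(0, 9, "+")])
        with pytest.raises(ValueError):
            classify_coding_effect(sub(10, "G", "A"), g)


class TestExpectedNSRatio:
    def test_lysine_repeat_closed_form(self):
        # only AAA->AAG (a transition) is synonymous: NS:S = (2*2+6)/2 = 5
        g = AnnotatedGenome("AAA" * 20, [CDS(0, 60, "+")])
        assert expected_ns_ratio(g, titv=1.0, ti_weight_factor=2.0) == pytest.approx(5.0)

    def test_fourfold_degenerate_equal_weights_closed_form(self):
        # glycine GGG: all 3 third-position changes synonymous; with
        # w_ti == w_tv the ratio is 6 NS : 3 S = 2
        g = AnnotatedGenome("GGG" * 10, [CDS(0, 30, "+")])
        assert expected_ns_ratio(g, titv=0.5, ti_weight_factor=2.0) == pytest.approx(2.0)

    def test_matches_independent_enumerator_on_synthetic_genome(self, tiny_genome):
        for titv in (1.0, 1.84):
            mine = expected_ns_ratio(tiny_genome, titv)
            oracle = brute_force_ns_ratio(tiny_genome, titv)
            assert mine == pytest.approx(oracle, rel=1e-12)

    def test_requires_cds_and_positive_titv(self):
        g = AnnotatedGenome("AAAA", [])
        with pytest.raises(ValueError):
            expected_ns_ratio(g, 1.0)
        g2 = AnnotatedGenome("AAA", [CDS(0, 3, "+")])
        with pytest.raises(ValueError):
            expected_ns_ratio(g2, math.inf)


class TestNSRatioTest:
    def test_exact_match_gives_zero_statistic(self):
        stat, df, p = ns_ratio_test(30, 10, 3.0)
        assert stat == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_goodness_of_fit_from_counts(self):
        stat, df, p = ns_ratio_test(38, 25, 2.76)
        assert stat == pytest.approx(5.52, abs=0.01)
        assert df == 1 and p < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ns_ratio_test(0, 0, 2.0)
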