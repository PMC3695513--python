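"""Expected false positives, ranking curves, enrichment and bias statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clanoverlap import (
    UndefinedResultError,
    bias_flag_families,
    conditional_track_overlap,
    cumulative_overlap_curve,
    expected_false_positives,
    families_for_fraction,
    flag_enrichment,
    flag_enrichment_from_counts,
    ga_to_evalue,
    greedy_assign,
    overrepresentation_curve,
    residue_bias_proportions,
)
from clanoverlap.assignment import AssignmentResult
from clanoverlap.labeling import index_tracks
from clanoverlap.model import FamilyCalibration, FamilyLabelSet, FeatureTrack

from conftest import mk_hit


class TestExpectedFalsePositives:
    def test_study_scale_worked_example(self):
        # 13 356 families at thresholds of 0.01: 133.56 + 1.3356
        value = expected_false_positives(13356, 0.01, 0.01)
        assert value == pytest.approx(134.8956)
        assert round(value) == 135

    def test_zero_sequence_threshold(self):
        assert expected_false_positives(5000, 0.0, 0.1) == 0.0

    def test_hand_evaluation(self):
        assert expected_false_positives(100, 0.1, 0.1) == pytest.approx(11.0)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            expected_false_positives(-1, 0.01, 0.01)
        with pytest.raises(ValueError):
            expected_false_positives(10, -0.01, 0.01)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        n=st.integers(0, 10**5),
        e1=st.floats(0, 1),
        e2=st.floats(0, 1),
        scale=st.integers(2, 10),
    )
    def test_linear_in_n_and_monotone(self, n, e1, e2, scale):
        base = expected_false_positives(n, e1, e2)
        assert expected_false_positives(n * scale, e1, e2) == pytest.approx(scale * base)
        assert expected_false_positives(n, min(e1 * scale, 1.0), e2) >= base - 1e-12


def result_with_counts(counts: dict[str, int]) -> AssignmentResult:
    mapping = {}
    for fam, k in counts.items():
        for i in range(k):
            mapping[mk_hit(seq=f"s{fam}_{i}", fam=fam)] = fam
    return AssignmentResult(domain_to_family=mapping)


class TestCumulativeCurve:
    def test_hand_cumulative_sum(self):
        curve = cumulative_overlap_curve(
            result_with_counts({"PF1": 5, "PF2": 3, "PF3": 2})
        )
        assert curve.families == ("PF1", "PF2", "PF3")
        assert curve.cumulative == pytest.approx((0.5, 0.8, 1.0))

    def test_single_family(self):
        curve = cumulative_overlap_curve(result_with_counts({"PF1": 4}))
        assert curve.cumulative == pytest.approx((1.0,))

    def test_ties_ordered_by_accession_and_strictly_increasing(self):
        curve = cumulative_overlap_curve(
            result_with_counts({"PF2": 2, "PF1": 2, "PF3": 2})
        )
        assert curve.families == ("PF1", "PF2", "PF3")
        assert all(b > a for a, b in zip(curve.cumulative, curve.cumulative[1:]))
        assert curve.cumulative[-1] == pytest.approx(1.0)

    def test_families_for_fraction(self):
        curve = cumulative_overlap_curve(
            result_with_counts({"PF1": 5, "PF2": 3, "PF3": 2})
        )
        assert families_for_fraction(curve, 0.5) == 1
        assert families_for_fraction(curve, 0.75) == 2
        assert families_for_fraction(curve, 1.0) == 3

    def test_empty_curve_is_undefined(self):
        empty = cumulative_overlap_curve(AssignmentResult())
        assert empty.families == ()
        with pytest.raises(UndefinedResultError):
            families_for_fraction(empty, 0.5)


def label_universe(n: int, labelled: set[int]) -> dict[str, FamilyLabelSet]:
    return {
        f"PF{i:04d}": FamilyLabelSet(f"PF{i:04d}", cc20=(i in labelled))
        for i in range(n)
    }


class TestOverrepresentation:
    def test_hand_ratio(self):
        # 5 of the first 10 ranked are labelled; 10 of 100 overall -> fold 5
        labels = label_universe(100, labelled=set(range(5)) | set(range(50, 55)))
        ranked = [f"PF{i:04d}" for i in range(10)]
        curve = overrepresentation_curve(ranked, labels, list(labels))
        assert curve.fold_at("cc20", 10) == pytest.approx((5 / 10) / (10 / 100))

    def test_uniform_label_gives_fold_one_at_full_rank(self):
        labels = label_universe(40, labelled=set(range(0, 40, 4)))
        ranked = sorted(labels)
        curve = overrepresentation_curve(ranked, labels, ranked)
        assert curve.fold_at("cc20", 40) == pytest.approx(1.0)

    def test_absent_label_reported_missing(self):
        labels = label_universe(10, labelled=set())
        curve = overrepresentation_curve(sorted(labels), labels, sorted(labels))
        assert "cc20" not in curve.folds


CC = FeatureTrack("s1", "coiled_coil", ((1, 22),))
DIS = FeatureTrack("s1", "disorder", ((10, 40),))


class TestResidueProportions:
    def test_partial_coverage(self):
        props = residue_bias_proportions([("s1", 1, 100)], [CC])
        assert props["coiled_coil"] == pytest.approx(0.22)
        assert props["transmembrane"] == 0.0

    def test_full_coverage_and_region_union(self):
        # two overlapping regions count shared residues once
        props = residue_bias_proportions(
            [("s1", 1, 15), ("s1", 10, 22)], [CC]
        )
        assert props["coiled_coil"] == pytest.approx(1.0)

    def test_zero_regions_undefined(self):
        with pytest.raises(UndefinedResultError):
            residue_bias_proportions([], [CC])

    def test_proportions_bounded(self):
        props = residue_bias_proportions([("s1", 1, 50)], [CC, DIS])
        assert all(0 <= v <= 1 for v in props.values())


class TestConditionalOverlap:
    def test_hand_count(self):
        # disorder 10..19 (10 residues), coiled-coil covers 10..15 (6 of them)
        tracks = [
            FeatureTrack("s1", "disorder", ((10, 19),)),
            FeatureTrack("s1", "coiled_coil", ((5, 15),)),
        ]
        frac = conditional_track_overlap([("s1", 1, 100)], tracks, "disorder", "coiled_coil")
        assert frac == pytest.approx(0.6)

    def test_disjoint_and_identical_tracks(self):
        disjoint = [
            FeatureTrack("s1", "disorder", ((10, 19),)),
            FeatureTrack("s1", "coiled_coil", ((50, 60),)),
        ]
        assert conditional_track_overlap(
            [("s1", 1, 100)], disjoint, "disorder", "coiled_coil"
        ) == 0.0
        identical = [
            FeatureTrack("s1", "disorder", ((10, 19),)),
            FeatureTrack("s1", "coiled_coil", ((10, 19),)),
        ]
        assert conditional_track_overlap(
            [("s1", 1, 100)], identical, "disorder", "coiled_coil"
        ) == 1.0

    def test_no_given_residues_undefined(self):
        with pytest.raises(UndefinedResultError):
            conditional_track_overlap([("s1", 1, 100)], [CC], "disorder", "coiled_coil")


class TestBiasFlagging:
    def hits_with_ratios(self, fam, ratios, dom_e=1e-4):
        return [
            mk_hit(seq=f"s{i}", fam=fam, dom_e=dom_e, bit=100.0, bias=100.0 * r)
            for i, r in enumerate(ratios)
        ]

    def test_majority_biased_flagged(self):
        hits = self.hits_with_ratios("PF1", [0.2, 0.15, 0.05])
        assert bias_flag_families(hits) == {"PF1"}

    def test_unbiased_not_flagged(self):
        hits = self.hits_with_ratios("PF1", [0.0, 0.0, 0.0])
        assert bias_flag_families(hits) == set()

    def test_exact_half_is_not_flagged(self):
        hits = self.hits_with_ratios("PF1", [0.2, 0.05])
        assert bias_flag_families(hits) == set()

    def test_only_qualifying_hits_considered(self):
        biased_but_insignificant = self.hits_with_ratios("PF1", [0.3, 0.3], dom_e=0.5)
        assert bias_flag_families(biased_but_insignificant, threshold=0.01) == set()


class TestFlagEnrichment:
    def test_study_scale_counts(self):
        # 36/96 promiscuous flagged vs 744/13356 overall: ~6.73-fold
        fold = flag_enrichment_from_counts(36, 96, 744, 13356)
        assert fold == pytest.approx(6.7319, abs=1e-3)
        assert fold > 6

    def test_set_and_count_routes_agree(self):
        universe = {f"F{i}" for i in range(100)}
        promiscuous = {f"F{i}" for i in range(10)}
        flagged = {f"F{i}" for i in range(5)} | {f"F{i}" for i in range(50, 55)}
        fold = flag_enrichment(flagged, promiscuous, universe)
        assert fold == pytest.approx(flag_enrichment_from_counts(5, 10, 10, 100))

    def test_fully_flagged_promiscuous(self):
        universe = {f"F{i}" for i in range(100)}
        promiscuous = {f"F{i}" for i in range(10)}
        flagged = promiscuous  # 10% flagged overall, 100% of promiscuous
        assert flag_enrichment(flagged, promiscuous, universe) == pytest.approx(10.0)

    def test_empty_denominators_undefined(self):
        with pytest.raises(UndefinedResultError):
            flag_enrichment(set(), {"F1"}, {"F1"})


class TestGatheringThresholdConversion:
    def test_at_tau_equals_database_size(self):
        calib = FamilyCalibration("PF1", ga_bits=12.5, lam=0.7, tau=12.5, db_size=54321)
        assert ga_to_evalue(calib) == pytest.approx(54321.0)

    def test_powers_of_two(self):
        calib = FamilyCalibration("PF1", ga_bits=10.0, lam=math.log(2), tau=0.0, db_size=1024)
        assert ga_to_evalue(calib) == pytest.approx(1.0)

    def test_strictly_decreasing_in_score(self):
        es = [
            ga_to_evalue(FamilyCalibration("PF1", x, 0.7, 5.0, 10**6))
            for x in (10.0, 20.0, 30.0)
        ]
        assert es[0] > es[1] > es[2]
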