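"""Condensation of overlapping peptides and MHC class assignment."""

import random

import numpy as np
import pytest

from conftest import exhaustive_superstrings, random_overlapping_component, rec
from maedeconv.epitope_assembly import (
    CondensationError,
    classify_epitopes,
    condense_peptides,
    drop_short_peptides,
)


def coord_rec(protein, start, seq, **kw):
    return rec(seq, protein_id=protein, start=start, end=start + len(seq) - 1, **kw)


class TestCoordinateMode:
    def test_overlapping_intervals_merge_to_union_span(self):
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLG"  # positions 1..28
        records = [
            coord_rec("X", 10, protein[9:18]),   # 10-18
            coord_rec("X", 12, protein[11:22]),  # 12-22
        ]
        (ep,) = condense_peptides(records, mode="coordinates")
        assert (ep.start, ep.end) == (10, 22)
        assert len(ep.sequence) == 13
        assert ep.sequence == protein[9:22]

    def test_disjoint_intervals_stay_separate(self):
        records = [
            coord_rec("X", 10, "KLVANNTRL"),
            coord_rec("X", 30, "VANNTRLEF"),
        ]
        eps = condense_peptides(records, mode="coordinates")
        assert len(eps) == 2
        assert {(e.start, e.end) for e in eps} == {(10, 18), (30, 38)}

    def test_different_proteins_never_merge(self):
        records = [coord_rec("X", 10, "KLVANNTRL"), coord_rec("Y", 10, "KLVANNTRL")]
        assert len(condense_peptides(records, mode="coordinates")) == 2

    def test_multi_mapping_uses_smallest_accession(self):
        (ep,) = condense_peptides(
            [coord_rec("Q9;A1", 5, "KLVANNTRL")], mode="coordinates"
        )
        assert ep.protein_id == "A1"

    def test_conflicting_residues_raise(self):
        records = [
            coord_rec("X", 10, "KLVANNTRL"),
            coord_rec("X", 12, "XXNNTRLEF".replace("X", "W")),  # disagrees at 12-13
        ]
        with pytest.raises(CondensationError, match="conflicting"):
            condense_peptides(records, mode="coordinates")

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates mode"):
            condense_peptides([rec("KLVANNTRL")], mode="coordinates")


class TestStringMode:
    def test_suffix_prefix_merge(self):
        records = [rec("KLVANNTRL"), rec("VANNTRLEF")]
        (ep,) = condense_peptides(records, mode="string", min_overlap=5)
        assert ep.sequence == "KLVANNTRLEF"
        # independent check: the exhaustive merge-order oracle agrees
        assert exhaustive_superstrings(("KLVANNTRL", "VANNTRLEF"), 5) == {
            "KLVANNTRLEF"
        }

    def test_containment_merge(self):
        records = [rec("KLVANNTRLEF"), rec("VANNTRL")]
        (ep,) = condense_peptides(records, mode="string", min_overlap=5)
        assert ep.sequence == "KLVANNTRLEF"
        assert ep.n_constituents == 2

    def test_short_overlap_does_not_merge(self):
        records = [rec("KLVANNTRL"), rec("NTRLEFGHI")]  # overlap 4 < 5
        assert len(condense_peptides(records, mode="string", min_overlap=5)) == 2

    def test_conflicting_component_raises(self):
        # GGGGGHHHHH overlaps both HHHHHKKKKK and HHHHHRRRRR at offset 5;
        # column 11 would need both K and R
        records = [rec("GGGGGHHHHH"), rec("HHHHHKKKKK"), rec("HHHHHRRRRR")]
        with pytest.raises(CondensationError, match="conflicting"):
            condense_peptides(records, mode="string", min_overlap=5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no peptide"):
            condense_peptides([], mode="string")


class TestCondensationProperties:
    def test_partition_every_record_in_exactly_one_epitope(self):
        rng = np.random.default_rng(11)
        span, intervals = random_overlapping_component(rng)
        records = [
            coord_rec("P", s + 1, span[s:e], cell_line=f"c{i % 2}")
            for i, (s, e) in enumerate(intervals)
        ]
        eps = condense_peptides(records, mode="coordinates")
        assert sum(len(e.constituents) for e in eps) == len(records)

    @pytest.mark.parametrize("n_shuffles", [8])
    def test_permutation_invariance(self, n_shuffles):
        rng = np.random.default_rng(5)
        span, intervals = random_overlapping_component(rng)
        records = [coord_rec("P", s + 1, span[s:e]) for s, e in intervals]
        baseline = [
            (e.sequence, e.start, e.end)
            for e in condense_peptides(records, mode="coordinates")
        ]
        shuffler = random.Random(0)
        for _ in range(n_shuffles):
            shuffled = records[:]
            shuffler.shuffle(shuffled)
            result = [
                (e.sequence, e.start, e.end)
                for e in condense_peptides(shuffled, mode="coordinates")
            ]
            assert result == baseline

    def test_string_mode_reproduces_coordinate_mode(self):
        """With known overlaps >= min_overlap, both modes agree."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            span, intervals = random_overlapping_component(rng, min_overlap=5)
            records = [coord_rec("P", s + 1, span[s:e]) for s, e in intervals]
            by_coord = {e.sequence for e in condense_peptides(records, "coordinates")}
            by_string = {
                e.sequence
                for e in condense_peptides(records, "string", min_overlap=5)
            }
            assert by_string == by_coord == {span}

    def test_exhaustive_merge_order_oracle(self):
        """All merge orders reach the same maximal sequence the
        implementation reports (components of <= 6 peptides)."""
        rng = np.random.default_rng(37)
        for _ in range(25):
            span, intervals = random_overlapping_component(rng, max_peptides=6)
            seqs = tuple({span[s:e] for s, e in intervals})
            reachable = exhaustive_superstrings(seqs, 5)
            eps = condense_peptides(
                [rec(s) for s in seqs], mode="string", min_overlap=5
            )
            assert len(eps) == 1
            assert eps[0].sequence in reachable
            assert len(eps[0].sequence) == max(len(r) for r in reachable)


class TestClassification:
    def test_mhc1_by_length(self):
        (ep,) = condense_peptides(
            [coord_rec("P", 1, "KLVANNTRLF", spectral_count=5)], "coordinates"
        )
        (out,) = classify_epitopes([ep])
        assert out.mhc_class == "I"

    def test_mhc2_needs_three_distinct_constituents(self):
        span = "KLVANNTRLEFGHIK"  # 15-mer
        records = [
            coord_rec("P", 1, span, spectral_count=3),
            coord_rec("P", 1, span[:13], spectral_count=3),
            coord_rec("P", 3, span[2:], spectral_count=3),
        ]
        (ep,) = condense_peptides(records, "coordinates")
        (out,) = classify_epitopes([ep])
        assert out.mhc_class == "II"

    def test_low_total_count_rejected(self):
        (ep,) = condense_peptides(
            [coord_rec("P", 1, "KLVANNTRLF", spectral_count=2)], "coordinates"
        )
        (out,) = classify_epitopes([ep])
        assert out.mhc_class == "rejected"

    def test_single_peptide_15mer_rejected(self):
        (ep,) = condense_peptides(
            [coord_rec("P", 1, "KLVANNTRLEFGHIK", spectral_count=9)], "coordinates"
        )
        (out,) = classify_epitopes([ep])
        assert out.mhc_class == "rejected"

    def test_span_beyond_class_ii_maximum_rejected(self):
        seq = "KLVANNTRLEFGHIKWMPQR" + "A"  # 21-mer
        (ep,) = condense_peptides(
            [coord_rec("P", 1, seq, spectral_count=9)], "coordinates"
        )
        (out,) = classify_epitopes([ep])
        assert out.mhc_class == "rejected"

    def test_overlapping_class_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_epitopes([], mhc1_range=(9, 12), mhc2_range=(12, 20))

    def test_short_peptides_dropped_before_condensation(self):
        records = [rec("KLVANNTR"), rec("KLVANNTRL")]  # 8-mer and 9-mer
        kept = drop_short_peptides(records)
        assert [r.sequence for r in kept] == ["KLVANNTRL"]
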