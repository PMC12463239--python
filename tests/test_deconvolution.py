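"""Theoretical allele profiles, epitope-to-allele assignment, traceability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maedeconv.deconvolution import (
    AlleleProfile,
    Genotype,
    assign_epitope_alleles,
    locus_of_allele,
    read_genotype_table,
    theoretical_profiles,
    traceable_allele_count,
    traceability_by_panel_size,
    write_genotype_table,
)


def family():
    """Seven-line panel: father, mother, three children at one locus."""
    hap = {
        "father": ("A*01", "A*02"),
        "mother": ("A*03", "A*04"),
        "child1": ("A*01", "A*03"),
        "child2": ("A*01", "A*04"),
        "child3": ("A*02", "A*03"),
    }
    return [Genotype(cell_line=c, alleles={"A": pair}) for c, pair in hap.items()]


class TestTheoreticalProfiles:
    def test_presence_follows_genotypes(self):
        profiles = {p.allele: p.presence for p in theoretical_profiles(family())}
        # A*01: father and children 1, 2; panel order father..child3
        assert profiles["A*01"] == (1, 0, 1, 1, 0)
        assert profiles["A*02"] == (1, 0, 0, 0, 1)

    def test_homozygous_everywhere_gives_all_ones(self):
        genos = [
            Genotype(cell_line=c, alleles={"B": ("B*07", "B*07")})
            for c in ("x", "y", "z")
        ]
        (p,) = theoretical_profiles(genos)
        assert p.presence == (1, 1, 1)

    def test_missing_locus_names_line(self):
        genos = family() + [Genotype(cell_line="odd", alleles={"B": ("B*1", "B*2")})]
        with pytest.raises(ValueError, match="odd"):
            theoretical_profiles(genos, loci=["A"])

    def test_all_zero_profile_is_invalid(self):
        with pytest.raises(ValueError, match="no cell line"):
            AlleleProfile(allele="A*99", presence=(0, 0, 0))

    def test_genotype_table_roundtrip(self, tmp_path):
        path = tmp_path / "geno.tsv"
        write_genotype_table(family(), path)
        back = read_genotype_table(path)
        assert [g.cell_line for g in back] == [g.cell_line for g in family()]
        assert back[0].alleles["A"] == ("A*01", "A*02")


class TestAssignEpitopeAlleles:
    def test_exact_match_returns_singleton(self):
        profiles = theoretical_profiles(family())
        observed = [3.2, 0.0, 1.1, 0.4, 0.0]  # binarizes to A*01's profile
        assert assign_epitope_alleles(observed, profiles) == {"A*01"}

    def test_cosegregating_duplicates_stay_ambiguous(self):
        profiles = [
            AlleleProfile("A*01", (1, 0, 1)),
            AlleleProfile("B*08", (1, 0, 1)),  # same haplotype, same profile
            AlleleProfile("A*02", (0, 1, 1)),
        ]
        assert assign_epitope_alleles([5.0, 0.0, 2.0], profiles) == {"A*01", "B*08"}

    def test_ubiquitous_pattern_with_no_allele_is_contaminant(self):
        profiles = theoretical_profiles(family())
        assert assign_epitope_alleles([1.0] * 5, profiles) == set()

    def test_max_mismatch_tolerates_dropout(self):
        profiles = theoretical_profiles(family())
        observed = [3.2, 0.0, 0.0, 0.4, 0.0]  # A*01 with one line lost
        assert assign_epitope_alleles(observed, profiles, max_mismatch=0) == set()
        assert "A*01" in assign_epitope_alleles(observed, profiles, max_mismatch=1)

    def test_floor_discards_trace_signal(self):
        profiles = theoretical_profiles(family())
        observed = [3.2, 0.01, 1.1, 0.4, 0.01]
        assert assign_epitope_alleles(observed, profiles, floor=0.05) == {"A*01"}

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lines"):
            assign_epitope_alleles([1.0, 0.0], theoretical_profiles(family()))


class TestTraceability:
    def test_all_distinct_profiles_all_traceable(self):
        profiles = [
            AlleleProfile("a1", (1, 1, 0)),
            AlleleProfile("a2", (1, 0, 1)),
            AlleleProfile("a3", (0, 1, 1)),
        ]
        count, names = traceable_allele_count(profiles)
        assert count == 3 and names == ["a1", "a2", "a3"]

    def test_duplicates_are_untraceable(self):
        profiles = [
            AlleleProfile("a1", (1, 1, 0)),
            AlleleProfile("a2", (1, 1, 0)),
            AlleleProfile("a3", (0, 1, 1)),
        ]
        count, names = traceable_allele_count(profiles)
        assert count == 1 and names == ["a3"]

    def test_panel_extension_splits_duplicate_pair(self):
        before = [
            AlleleProfile("a1", (1, 1, 0)),
            AlleleProfile("a2", (1, 1, 0)),
        ]
        after = [
            AlleleProfile("a1", (1, 1, 0, 1)),
            AlleleProfile("a2", (1, 1, 0, 0)),
        ]
        assert traceable_allele_count(before)[0] == 0
        assert traceable_allele_count(after)[0] == 2

    def test_per_locus_uniqueness_ignores_other_loci(self):
        profiles = [
            AlleleProfile("A*01", (1, 1, 0)),
            AlleleProfile("B*08", (1, 1, 0)),  # co-segregating, other locus
        ]
        assert traceable_allele_count(profiles)[0] == 0
        locus_of = {p.allele: locus_of_allele(p.allele) for p in profiles}
        assert traceable_allele_count(profiles, locus_of=locus_of)[0] == 2

    def test_brute_force_uniqueness_oracle(self):
        """Pairwise-comparison oracle agrees on random panels <= 32 alleles."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(2, 33))
            lines = int(rng.integers(1, 7))
            vecs = rng.integers(0, 2, size=(k, lines))
            vecs[:, 0] = 1  # keep profiles non-zero
            profiles = [
                AlleleProfile(f"x{i}", tuple(int(v) for v in vecs[i]))
                for i in range(k)
            ]
            count, names = traceable_allele_count(profiles)
            expected = [
                p.allele
                for i, p in enumerate(profiles)
                if all(
                    profiles[j].presence != p.presence
                    for j in range(k)
                    if j != i
                )
            ]
            assert count == len(expected)
            assert names == sorted(expected)

    def test_panel_size_report_shape_and_bounds(self):
        table = traceability_by_panel_size(family())
        assert len(table) == len(family())
        assert (table["n_traceable"] <= table["n_alleles"]).all()
        per_locus = traceability_by_panel_size(family(), per_locus=True)
        # within-locus uniqueness is never stricter than across-loci
        assert (per_locus["n_traceable"] >= table["n_traceable"]).all()


@settings(max_examples=60, deadline=None)
@given(
    st.integers(min_value=2, max_value=12),  # alleles
    st.integers(min_value=1, max_value=6),   # initial lines
    st.integers(min_value=1, max_value=4),   # appended lines
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_traceable_count_monotone_under_panel_extension(k, lines, extra, seed):
    """Appending cell lines (extending every presence vector) never
    decreases the traceable-allele count."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, size=(k, lines))
    base[:, 0] = 1
    ext = rng.integers(0, 2, size=(k, extra))
    short = [AlleleProfile(f"x{i}", tuple(map(int, base[i]))) for i in range(k)]
    long = [
        AlleleProfile(f"x{i}", tuple(map(int, np.concatenate([base[i], ext[i]]))))
        for i in range(k)
    ]
    assert traceable_allele_count(long)[0] >= traceable_allele_count(short)[0]
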