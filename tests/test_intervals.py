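"""Interval set algebra: overlap semantics, partitions, merging, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_peaks, random_intervals
from _oracles import brute_overlapping, brute_symmetric, brute_unique

from peakfactor.intervals import (
    PeakSet,
    filter_redundant,
    idr_filter,
    overlapping_with,
    overlaps,
    replicate_reproducible,
    symmetric_unique,
    tn5_shift,
    union_span,
    unique_against,
)
from peakfactor.io_formats import GenomicInterval


def coords(ps):
    return sorted(iv.coords for iv in ps)


class TestOverlaps:
    @pytest.mark.parametrize("a,b,expected", [
        (("chr1", 100, 200), ("chr1", 150, 250), True),
        (("chr1", 100, 200), ("chr1", 200, 300), False),  # half-open abut
        (("chr1", 100, 200), ("chr2", 100, 200), False),
        (("chr1", 100, 200), ("chr1", 199, 300), True),
    ])
    def test_overlap_primitive(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected

    def test_min_overlap_fraction_of_bases(self):
        a, b = GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 90, 200)
        assert overlaps(a, b, min_overlap=10)
        assert not overlaps(a, b, min_overlap=11)


class TestUniqueAndConserved:
    def test_unique_removes_overlapping(self):
        q = make_peaks([("chr1", 100, 200)])
        r = make_peaks([("chr1", 150, 250)])
        assert len(unique_against(q, r)) == 0
        assert coords(overlapping_with(q, r)) == [("chr1", 100, 200)]

    def test_unique_keeps_nonoverlapping(self):
        q = make_peaks([("chr1", 100, 200), ("chr1", 500, 600)])
        r = make_peaks([("chr1", 550, 560)])
        assert coords(unique_against(q, r)) == [("chr1", 100, 200)]

    def test_empty_inputs_allowed(self):
        q = make_peaks([("chr1", 0, 10)])
        assert len(unique_against(q, PeakSet())) == 1
        assert len(unique_against(PeakSet(), q)) == 0
        assert len(overlapping_with(PeakSet(), q)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = PeakSet(random_intervals(rng, 400, chroms=("chr1", "chr2")), "q")
        r = PeakSet(random_intervals(rng, 400, chroms=("chr1", "chr2")), "r")
        assert coords(unique_against(q, r)) == \
            sorted(iv.coords for iv in brute_unique(list(q), list(r)))
        assert coords(overlapping_with(q, r)) == \
            sorted(iv.coords for iv in brute_overlapping(list(q), list(r)))
        assert coords(symmetric_unique(q, r)) == \
            sorted(iv.coords for iv in brute_symmetric(list(q), list(r)))

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = PeakSet(random_intervals(rng, 300), "q")
        r = PeakSet(random_intervals(rng, 300), "r")
        u, o = unique_against(q, r), overlapping_with(q, r)
        assert len(u) + len(o) == len(q)
        assert set(coords(u)).isdisjoint(coords(o))
        assert sorted(coords(u) + coords(o)) == coords(q)

    def test_min_overlap_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        q = PeakSet(random_intervals(rng, 200), "q")
        r = PeakSet(random_intervals(rng, 200), "r")
        for mo in (5, 50):
            assert coords(unique_against(q, r, mo)) == \
                sorted(iv.coords for iv in brute_unique(list(q), list(r), mo))


class TestSymmetricUnique:
    def test_identical_sets_empty(self):
        p = make_peaks([("chr1", 100, 200)], "P")
        q = make_peaks([("chr1", 100, 200)], "Q")
        assert len(symmetric_unique(p, q)) == 0

    def test_disjoint_sets_both_kept_with_provenance(self):
        p = make_peaks([("chr1", 0, 50)], "P")
        q = make_peaks([("chr1", 100, 150)], "Q")
        result = symmetric_unique(p, q)
        assert len(result) == 2
        assert result.origins[("chr1", 0, 50)] == "P"
        assert result.origins[("chr1", 100, 150)] == "Q"


class TestFilterRedundant:
    def test_exact_duplicates_dropped(self):
        ps = PeakSet([GenomicInterval("chr1", 100, 200, "a"),
                      GenomicInterval("chr1", 100, 200, "b")])
        assert coords(filter_redundant(ps)) == [("chr1", 100, 200)]

    def test_overlapping_merged_to_union_span(self):
        ps = make_peaks([("chr1", 100, 250), ("chr1", 200, 400)])
        assert coords(filter_redundant(ps)) == [("chr1", 100, 400)]

    @pytest.mark.parametrize("seed", range(5))
    def test_output_has_no_internal_overlaps_and_idempotent(self, seed):
        rng = np.random.default_rng(200 + seed)
        ps = PeakSet(random_intervals(rng, 500, chroms=("chr1", "chr2")))
        merged = filter_redundant(ps)
        ivs = list(merged)
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                assert not overlaps(ivs[i], ivs[j])
        assert coords(filter_redundant(merged)) == coords(merged)
        assert len(merged) <= len(ps)

    def test_spans_never_fabricated(self):
        """Every output span is an input span or a union of overlapping inputs."""
        rng = np.random.default_rng(3)
        ps = PeakSet(random_intervals(rng, 300))
        inputs = coords(ps)
        for chrom, s, e in coords(filter_redundant(ps)):
            members = [(c, a, b) for (c, a, b) in inputs if c == chrom and a < e and b > s]
            assert min(a for _, a, _ in members) == s
            assert max(b for _, _, b in members) == e


class TestUnionSpan:
    def test_extreme_coordinates(self):
        merged = union_span(GenomicInterval("chr1", 100, 250),
                            GenomicInterval("chr1", 200, 400))
        assert merged.coords == ("chr1", 100, 400)

    def test_commutative_and_idempotent(self):
        a = GenomicInterval("chr1", 100, 250)
        b = GenomicInterval("chr1", 200, 400)
        assert union_span(a, b).coords == union_span(b, a).coords
        assert union_span(a, a).coords == a.coords

    def test_cross_chromosome_error(self):
        with pytest.raises(ValueError, match="different chromosomes"):
            union_span(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))

    def test_non_overlapping_error(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            union_span(GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30))


class TestIdrFilter:
    def test_boundary_is_inclusive(self):
        ivs = [GenomicInterval("chr1", i * 1000, i * 1000 + 100, idr=v)
               for i, v in enumerate((0.01, 0.05, 0.06))]
        kept = idr_filter(PeakSet(ivs), 0.05)
        assert sorted(iv.idr for iv in kept) == [0.01, 0.05]

    def test_threshold_extremes(self):
        ivs = [GenomicInterval("chr1", i * 1000, i * 1000 + 100, idr=0.2)
               for i in range(3)]
        assert len(idr_filter(PeakSet(ivs), 1.0)) == 3
        assert len(idr_filter(PeakSet(ivs), 0.0)) == 0

    def test_missing_idr_is_error(self):
        ps = make_peaks([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="no .*IDR"):
            idr_filter(ps)


class TestReplicateReproducible:
    def test_union_span_applied(self):
        r1 = make_peaks([("chr1", 100, 200)])
        r2 = make_peaks([("chr1", 150, 260)])
        assert coords(replicate_reproducible(r1, r2)) == [("chr1", 100, 260)]

    def test_disjoint_replicates_empty(self):
        r1 = make_peaks([("chr1", 100, 200)])
        r2 = make_peaks([("chr1", 500, 600)])
        assert len(replicate_reproducible(r1, r2)) == 0

    def test_identical_replicates_identity(self):
        r = make_peaks([("chr1", 100, 200), ("chr2", 0, 50)])
        assert coords(replicate_reproducible(r, r)) == coords(r)

    def test_matches_bruteforce_support(self):
        rng = np.random.default_rng(5)
        r1 = PeakSet(random_intervals(rng, 300), "r1")
        r2 = PeakSet(random_intervals(rng, 300), "r2")
        supported = {iv.coords for iv in brute_overlapping(list(r1), list(r2))}
        result = replicate_reproducible(r1, r2)
        assert len(result) <= len(supported)  # union-merge may deduplicate spans
        for iv in result:
            mates = [m for m in r2 if overlaps(iv, m)]
            assert mates, "every output peak must be supported by rep2"


class TestTn5Shift:
    def test_plus_strand_shifted_4bp(self):
        assert tn5_shift([("chr1", 1000, "+")]) == [("chr1", 1004, "+")]

    def test_minus_strand_unchanged(self):
        assert tn5_shift([("chr1", 1000, "-")]) == [("chr1", 1000, "-")]

    def test_empty(self):
        assert tn5_shift([]) == []


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=30),
       st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=30))
def test_partition_property(starts_q, starts_r):
    """unique + conserved partition the query for arbitrary inputs."""
    q = PeakSet([GenomicInterval("chr1", s, s + l) for s, l in starts_q], "q")
    r = PeakSet([GenomicInterval("chr1", s, s + l) for s, l in starts_r], "r")
    u, o = unique_against(q, r), overlapping_with(q, r)
    assert sorted(coords(u) + coords(o)) == coords(q)
    assert coords(u) == sorted(iv.coords for iv in brute_unique(list(q), list(r)))
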