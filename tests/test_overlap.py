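"""Venn partitioning, Jaccard arithmetic, random libraries, permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import v3cseq as v


def peakset(ids):
    return v.PeakSet("x", len(ids), [(fid, 1) for fid in ids])


intervals_strategy = st.lists(
    st.tuples(
        st.sampled_from(["c1", "c2"]),
        st.integers(min_value=0, max_value=300),
        st.integers(min_value=1, max_value=60),
    ).map(lambda t: (t[0], t[1], t[1] + t[2])),
    min_size=1,
    max_size=12,
)


def brute_force_jaccard(a, b):
    """Oracle: Jaccard over explicit covered-base sets."""
    cover = lambda ivs: {
        (chrom, pos) for chrom, start, end in ivs for pos in range(start, end)
    }
    ca, cb = cover(a), cover(b)
    return len(ca & cb) / len(ca | cb)


class TestVennPartition:
    def test_fragment_mode_enumeration(self):
        parts = v.venn_partition(
            peakset(["f1", "f2", "f3"]), peakset(["f2", "f3", "f4"])
        )
        assert parts.unique_a == {"f1"}
        assert parts.shared == {"f2", "f3"}
        assert parts.unique_b == {"f4"}

    def test_identical_sets_all_shared(self):
        parts = v.venn_partition(peakset(["f1", "f2"]), peakset(["f1", "f2"]))
        assert parts.unique_a == parts.unique_b == frozenset()
        assert parts.shared == {"f1", "f2"}

    def test_disjoint_sets_empty_shared(self):
        parts = v.venn_partition(peakset(["f1"]), peakset(["f2"]))
        assert parts.shared == frozenset()

    def test_parts_disjoint_and_exhaustive(self):
        a, b = peakset(["f1", "f2", "f3", "f5"]), peakset(["f2", "f4", "f5"])
        parts = v.venn_partition(a, b)
        groups = [parts.unique_a, parts.shared, parts.unique_b]
        assert sum(len(g) for g in groups) == len(set().union(*groups))
        assert set().union(*groups) == a.id_set | b.id_set

    def test_interval_mode_one_bp_overlap_counts(self):
        a = v.IntervalSet([("c1", 0, 100)], "a")
        b = v.IntervalSet([("c1", 99, 200)], "b")
        parts = v.venn_partition(a, b)
        assert parts.mode == "interval"
        assert len(parts.unique_a) == 0 and len(parts.unique_b) == 0
        assert len(parts.shared) == 2

    def test_mixed_modes_rejected(self):
        with pytest.raises(TypeError):
            v.venn_partition(peakset(["f1"]), v.IntervalSet([("c1", 0, 10)]))


class TestJaccard:
    def test_identity_is_one(self):
        a = v.IntervalSet([("c1", 0, 100), ("c2", 50, 80)], "a")
        assert v.jaccard(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = v.IntervalSet([("c1", 0, 100)], "a")
        b = v.IntervalSet([("c1", 200, 300)], "b")
        assert v.jaccard(a, b) == 0.0

    def test_half_overlap_is_one_third(self):
        a = v.IntervalSet([("c1", 0, 100)], "a")
        b = v.IntervalSet([("c1", 50, 150)], "b")
        assert v.jaccard(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            v.jaccard(v.IntervalSet([], "a"), v.IntervalSet([], "b"))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=intervals_strategy, b=intervals_strategy)
    def test_symmetry_merge_invariance_and_oracle(self, a, b):
        set_a, set_b = v.IntervalSet(a, "a"), v.IntervalSet(b, "b")
        observed = v.jaccard(set_a, set_b)
        assert observed == pytest.approx(v.jaccard(set_b, set_a))
        assert observed == pytest.approx(v.jaccard(set_a.merged(), set_b.merged()))
        rng = np.random.default_rng(0)
        shuffled = v.IntervalSet([a[i] for i in rng.permutation(len(a))], "a")
        assert observed == pytest.approx(v.jaccard(shuffled, set_b))
        assert observed == pytest.approx(brute_force_jaccard(a, b))


class TestRandomFragmentLibrary:
    SIZES = {"c1": 50_000, "c2": 30_000, "tiny": 1_000}

    def test_defaults_give_150_intervals_of_5kb(self):
        lib = v.random_fragment_library(self.SIZES, seed=0)
        assert len(lib) == 150
        assert all(end - start == 5000 for _, start, end in lib.intervals)

    def test_short_chromosomes_excluded(self):
        lib = v.random_fragment_library(self.SIZES, n=500, seed=1)
        assert {c for c, _, _ in lib.intervals} <= {"c1", "c2"}

    def test_start_bounds_on_single_chromosome(self):
        lib = v.random_fragment_library({"c1": 10_000}, n=300, size_bp=5000, seed=2)
        starts = [s for _, s, _ in lib.intervals]
        assert min(starts) >= 0 and max(starts) <= 5000

    def test_seed_reproducibility(self):
        a = v.random_fragment_library(self.SIZES, seed=7)
        b = v.random_fragment_library(self.SIZES, seed=7)
        assert a.intervals == b.intervals

    def test_no_eligible_chromosome_is_error(self):
        with pytest.raises(ValueError):
            v.random_fragment_library({"tiny": 100}, size_bp=5000, seed=0)


class TestJaccardPermutationTest:
    SIZES = {"c1": 200_000, "c2": 200_000}

    def test_add_one_lower_bound(self):
        """Observed above every permuted value gives p = 1/(n+1)."""
        a = v.IntervalSet([("c1", 0, 150_000)], "a")
        result = v.jaccard_permutation_test(a, a, self.SIZES, n_permutations=99, seed=0)
        assert result.observed == 1.0
        assert result.p_value == pytest.approx(1 / 100)

    def test_observed_below_all_permuted_gives_p_one(self):
        # a and b live on different chromosomes and b is a single interval
        # covering most of c2: every random interval overlaps it more than a does
        a = v.IntervalSet([("c1", 0, 1000)], "a")
        b = v.IntervalSet([("c2", 0, 190_000)], "b")
        result = v.jaccard_permutation_test(
            a, b, {"c2": 200_000}, n_permutations=49, seed=1
        )
        assert result.observed == 0.0
        assert result.p_value == 1.0

    def test_permuted_sets_matched_in_count_and_size(self):
        a = v.IntervalSet([("c1", 0, 5000)], "a")
        b = v.IntervalSet([("c1", i * 10_000, i * 10_000 + 2000) for i in range(5)], "b")
        result = v.jaccard_permutation_test(a, b, self.SIZES, n_permutations=10, seed=3)
        assert result.n_permutations == 10
        assert len(result.permuted) == 10

    def test_zero_permutations_rejected(self):
        a = v.IntervalSet([("c1", 0, 100)], "a")
        with pytest.raises(ValueError):
            v.jaccard_permutation_test(a, a, self.SIZES, n_permutations=0, seed=0)


class TestOverlapFraction:
    def test_thirty_percent_case(self):
        a = peakset([f"a{i}" for i in range(105)] + [f"s{i}" for i in range(45)])
        b = peakset([f"b{i}" for i in range(105)] + [f"s{i}" for i in range(45)])
        assert v.overlap_fraction(a, b) == pytest.approx(0.30)

    def test_identity_and_disjoint(self):
        a = peakset(["f1", "f2"])
        assert v.overlap_fraction(a, a) == 1.0
        assert v.overlap_fraction(a, peakset(["g1"])) == 0.0

    def test_empty_a_is_error(self):
        with pytest.raises(ValueError):
            v.overlap_fraction(peakset([]), peakset(["f1"]))
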