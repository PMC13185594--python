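"""Peak-set comparison statistics: Venn partitioning and Jaccard permutation tests.

Two top-N peak sets from different conditions are compared either as fragment
id sets (when both live on the same restriction-fragment universe) or as
genomic interval sets in bp.  Observed overlap is summarized by the Jaccard
index (intersection bp / union bp; 0 = no overlap, 1 = complete overlap) and
tested against a permutation null in which one set is replaced by randomly
placed intervals matched in count and mean size — by default 150 fragments of
5 kb, mirroring the matched-random-library convention for virus-associated
regions.  Empirical p-values use the add-one rule, so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .digest import parse_fragment_id
from .fragments import PeakSet

__all__ = [
    "IntervalSet",
    "VennPartition",
    "JaccardResult",
    "venn_partition",
    "jaccard",
    "random_fragment_library",
    "jaccard_permutation_test",
    "overlap_fraction",
]

Interval = Tuple[str, int, int]

DEFAULT_RANDOM_N = 150
DEFAULT_RANDOM_SIZE_BP = 5000


@dataclass
class IntervalSet:
    """A labelled set of genomic intervals (0-based half-open)."""

    intervals: List[Interval]
    label: str = ""

    @classmethod
    def from_peakset(cls, peaks: PeakSet, label: str = "") -> "IntervalSet":
        """Interval view of a fragment peak set (ids carry the coordinates)."""
        return cls(
            intervals=[parse_fragment_id(fid) for fid in peaks.ids],
            label=label or peaks.condition,
        )

    def merged(self) -> "IntervalSet":
        """Sorted copy with overlapping/abutting members merged."""
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        out: List[Interval] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            cur_start, cur_end = spans[0]
            for start, end in spans[1:]:
                if start <= cur_end:
                    cur_end = max(cur_end, end)
                else:
                    out.append((chrom, cur_start, cur_end))
                    cur_start, cur_end = start, end
            out.append((chrom, cur_start, cur_end))
        return IntervalSet(out, self.label)

    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.merged().intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class VennPartition:
    """Disjoint three-way partition of two peak/interval sets."""

    unique_a: Union[frozenset, IntervalSet]
    shared: Union[frozenset, IntervalSet]
    unique_b: Union[frozenset, IntervalSet]
    mode: str = "fragment"  # "fragment" (id equality) or "interval" (>=1 bp)


@dataclass
class JaccardResult:
    """Observed Jaccard index against its permutation null."""

    observed: float
    permuted: List[float]
    p_value: float
    n_permutations: int
    seed: int

    def summary(self) -> Dict[str, float]:
        perm = np.asarray(self.permuted)
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "permuted_mean": float(perm.mean()),
            "permuted_max": float(perm.max()),
            "seed": self.seed,
        }


def _overlaps_any(interval: Interval, merged: IntervalSet) -> bool:
    chrom, start, end = interval
    for mc, ms, me in merged.intervals:
        if mc == chrom and start < me and ms < end:
            return True
    return False


def venn_partition(a, b) -> VennPartition:
    """Partition two same-kind sets into unique-to-a, shared, unique-to-b.

    Fragment mode (two :class:`PeakSet`): shared means identical fragment id,
    since both sets live on the same fragment universe.  Interval mode (two
    :class:`IntervalSet`): a member is shared when it overlaps the other set
    by >= 1 bp; the shared part collects overlapping members from both sides.
    Mixing modes is an error.
    """
    if isinstance(a, PeakSet) and isinstance(b, PeakSet):
        ids_a, ids_b = a.id_set, b.id_set
        return VennPartition(
            unique_a=ids_a - ids_b,
            shared=ids_a & ids_b,
            unique_b=ids_b - ids_a,
            mode="fragment",
        )
    if isinstance(a, IntervalSet) and isinstance(b, IntervalSet):
        merged_a, merged_b = a.merged(), b.merged()
        unique_a = [iv for iv in a.intervals if not _overlaps_any(iv, merged_b)]
        unique_b = [iv for iv in b.intervals if not _overlaps_any(iv, merged_a)]
        shared = [iv for iv in a.intervals if _overlaps_any(iv, merged_b)] + [
            iv for iv in b.intervals if _overlaps_any(iv, merged_a)
        ]
        return VennPartition(
            unique_a=IntervalSet(unique_a, f"{a.label} only"),
            shared=IntervalSet(shared, "shared"),
            unique_b=IntervalSet(unique_b, f"{b.label} only"),
            mode="interval",
        )
    raise TypeError(
        "venn_partition requires two PeakSets or two IntervalSets, got "
        f"{type(a).__name__} and {type(b).__name__}"
    )


def _intersection_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Intersection bp of two *merged* interval sets (two-pointer sweep)."""
    by_chrom_b: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in b.intervals:
        by_chrom_b.setdefault(chrom, []).append((start, end))
    total = 0
    by_chrom_a: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in a.intervals:
        by_chrom_a.setdefault(chrom, []).append((start, end))
    for chrom, spans_a in by_chrom_a.items():
        spans_b = by_chrom_b.get(chrom)
        if not spans_b:
            continue
        i = j = 0
        while i < len(spans_a) and j < len(spans_b):
            a_start, a_end = spans_a[i]
            b_start, b_end = spans_b[j]
            lo, hi = max(a_start, b_start), min(a_end, b_end)
            if lo < hi:
                total += hi - lo
            if a_end <= b_end:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index of two interval sets.

    Sets are merged before the bp arithmetic, so the value is invariant to
    interval order and to pre-merged representation.  Two empty sets are an
    error (the index is undefined), not 0.
    """
    merged_a, merged_b = a.merged(), b.merged()
    bp_a, bp_b = (
        sum(e - s for _, s, e in merged_a.intervals),
        sum(e - s for _, s, e in merged_b.intervals),
    )
    if bp_a == 0 and bp_b == 0:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    inter = _intersection_bp(merged_a, merged_b)
    union = bp_a + bp_b - inter
    return inter / union


def random_fragment_library(
    chrom_sizes: Mapping[str, int],
    n: int = DEFAULT_RANDOM_N,
    size_bp: int = DEFAULT_RANDOM_SIZE_BP,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> IntervalSet:
    """Randomly placed fixed-size intervals across a genome.

    Chromosomes shorter than ``size_bp`` are excluded; each interval picks a
    chromosome with probability proportional to its eligible length
    (length - size_bp + 1) and a uniform start, independently of the others
    (self-overlap allowed).  Defaults mirror the matched null of 150 fragments
    of 5 kb.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    eligible = [(c, L) for c, L in sorted(chrom_sizes.items()) if L >= size_bp]
    if not eligible:
        raise ValueError(f"no chromosome is at least {size_bp} bp long")
    chroms = [c for c, _ in eligible]
    weights = np.array([L - size_bp + 1 for _, L in eligible], dtype=float)
    probs = weights / weights.sum()
    chosen = rng.choice(len(chroms), size=n, p=probs)
    intervals: List[Interval] = []
    for idx in chosen:
        chrom, length = eligible[idx]
        start = int(rng.integers(0, length - size_bp + 1))
        intervals.append((chrom, start, start + size_bp))
    return IntervalSet(intervals, label="random")


def jaccard_permutation_test(
    a: IntervalSet,
    b: IntervalSet,
    chrom_sizes: Mapping[str, int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> JaccardResult:
    """Permutation test of the observed Jaccard index.

    Each permuted value replaces ``b`` with a random library matched to it in
    interval count and mean size; the empirical p-value is
    ``(1 + #{permuted >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = jaccard(a, b)
    size_bp = max(1, round(np.mean([e - s for _, s, e in b.intervals])))
    rng = np.random.default_rng(seed)
    permuted: List[float] = []
    for _ in range(n_permutations):
        random_set = random_fragment_library(
            chrom_sizes, n=len(b.intervals), size_bp=size_bp, rng=rng
        )
        permuted.append(jaccard(a, random_set))
    exceed = sum(1 for v in permuted if v >= observed)
    p_value = (1 + exceed) / (1 + n_permutations)
    return JaccardResult(
        observed=observed,
        permuted=permuted,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


def overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of ``a``'s peaks shared with ``b`` (by fragment id)."""
    if len(a) == 0:
        raise ValueError("overlap_fraction undefined for an empty peak set")
    parts = venn_partition(a, b)
    return len(parts.shared) / len(a)
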