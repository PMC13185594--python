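"""Per-fragment interaction profiling and top-N peak calling.

A 4C-style junction read is a viral anchor (the inverse-PCR primer side)
followed by a host segment.  The pipeline here trims the anchor, locates the
host segment on the genome (an exact-match locator stands in for an external
aligner on synthetic data), assigns each aligned interval to the restriction
fragment containing its 5'-most base, and ranks fragments by raw read count to
call the top-N localization peaks (N = 150 by default, the convention for
virus-associated HindIII fragments).

Boundary-spanning reads are assigned by their 5' base because the informative
base of a junction read is its junction-proximal end; counts are raw (no
length normalization) and rank order breaks ties by (chrom, start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .digest import RestrictionFragmentLibrary, parse_fragment_id

__all__ = [
    "AlignedInterval",
    "Rejection",
    "InteractionProfile",
    "PeakSet",
    "trim_viral_anchor",
    "locate_exact",
    "ExactMatcher",
    "assign_to_fragments",
    "top_n",
    "profile_junction_reads",
    "peakset_intersection",
]

DEFAULT_PEAK_N = 150
MIN_LOCATE_LENGTH = 20


@dataclass(frozen=True)
class AlignedInterval:
    """One aligned read as a reference interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    read_id: str = ""
    mapq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end, got {self.chrom}:"
                f"{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class Rejection:
    """A read (or segment) excluded from profiling, with the reason why."""

    reason: str
    detail: str = ""


@dataclass
class InteractionProfile:
    """Per-fragment read counts for one virus/condition.

    Invariant: ``sum(counts.values()) + unassigned == total_reads``.
    """

    library_ref: str
    counts: Dict[str, int]
    unassigned: int
    total_reads: int

    def __post_init__(self) -> None:
        assigned = sum(self.counts.values())
        if assigned + self.unassigned != self.total_reads:
            raise ValueError(
                f"count conservation violated: {assigned} assigned + "
                f"{self.unassigned} unassigned != {self.total_reads} total"
            )


@dataclass
class PeakSet:
    """Top-N fragments for one condition, ordered by descending count."""

    condition: str
    n: int
    fragments: List[Tuple[str, int]]

    @property
    def ids(self) -> List[str]:
        return [fid for fid, _ in self.fragments]

    @property
    def id_set(self) -> frozenset:
        return frozenset(fid for fid, _ in self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


def trim_viral_anchor(
    read_seq: str, anchor: str, max_mismatches: int = 0
) -> Union[str, Rejection]:
    """Strip the viral anchor prefix from a junction read.

    The read prefix must match ``anchor`` with at most ``max_mismatches``
    Hamming mismatches (case-insensitive); on success the host-side suffix is
    returned, otherwise a :class:`Rejection` (rejection is a value, not an
    error).
    """
    if not anchor:
        raise ValueError("anchor must be nonempty")
    if len(read_seq) < len(anchor):
        return Rejection("short", "read shorter than anchor")
    prefix = read_seq[: len(anchor)].upper()
    mismatches = sum(a != b for a, b in zip(prefix, anchor.upper()))
    if mismatches > max_mismatches:
        return Rejection(
            "anchor_mismatch", f"{mismatches} mismatches > {max_mismatches}"
        )
    return read_seq[len(anchor):]


def locate_exact(
    segment: str, genome: Mapping[str, str], read_id: str = ""
) -> Union[AlignedInterval, Rejection]:
    """Locate a host segment by unique exact match (forward strand).

    A test-scale substitute for an external aligner: a unique occurrence
    yields its interval; zero or >=2 occurrences yield a rejection
    ("absent" / "ambiguous"), as do segments under 20 bp ("too_short").
    """
    if len(segment) < MIN_LOCATE_LENGTH:
        return Rejection("too_short", f"segment {len(segment)} bp < {MIN_LOCATE_LENGTH}")
    seg = segment.upper()
    hit: Optional[Tuple[str, int]] = None
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        i = seq.find(seg)
        while i != -1:
            if hit is not None:
                return Rejection("ambiguous", "segment occurs more than once")
            hit = (chrom, i)
            i = seq.find(seg, i + 1)
    if hit is None:
        return Rejection("absent", "segment not found in genome")
    chrom, start = hit
    return AlignedInterval(chrom, start, start + len(seg), read_id=read_id)


class ExactMatcher:
    """Memoized exact-match locator for bulk synthetic read location.

    Junction reads simulated from a fragment library have at most one distinct
    host segment per fragment, so caching by segment makes locating 10^5 reads
    cost one genome scan per unique segment.
    """

    def __init__(self, genome: Mapping[str, str]) -> None:
        self._genome = {c: s.upper() for c, s in genome.items()}
        self._cache: Dict[str, Union[AlignedInterval, Rejection]] = {}

    def locate(self, segment: str, read_id: str = "") -> Union[AlignedInterval, Rejection]:
        seg = segment.upper()
        cached = self._cache.get(seg)
        if cached is None:
            cached = locate_exact(seg, self._genome)
            self._cache[seg] = cached
        if isinstance(cached, Rejection):
            return cached
        return AlignedInterval(cached.chrom, cached.start, cached.end, read_id=read_id)


def assign_to_fragments(
    intervals: Iterable[AlignedInterval],
    library: RestrictionFragmentLibrary,
    library_ref: str = "",
    min_mapq: int = 0,
) -> InteractionProfile:
    """Count aligned intervals per restriction fragment.

    Each interval goes to the fragment containing its 5'-most base (its
    start); intervals on chromosomes absent from the library, or starting
    beyond the chromosome end, increment ``unassigned``.  Records with
    ``mapq`` below ``min_mapq`` are also left unassigned (default 0 keeps
    everything).  Conservation always holds:
    assigned + unassigned == number of input intervals.
    """
    counts: Dict[str, int] = {}
    unassigned = 0
    total = 0
    for iv in intervals:
        total += 1
        if min_mapq and iv.mapq is not None and iv.mapq < min_mapq:
            unassigned += 1
            continue
        frag = library.fragment_at(iv.chrom, iv.start)
        if frag is None:
            unassigned += 1
            continue
        counts[frag.fragment_id] = counts.get(frag.fragment_id, 0) + 1
    return InteractionProfile(
        library_ref=library_ref or f"{library.enzyme.name}:{len(library)}",
        counts=counts,
        unassigned=unassigned,
        total_reads=total,
    )


def profile_from_counts(
    library: RestrictionFragmentLibrary, counts: np.ndarray, library_ref: str = ""
) -> InteractionProfile:
    """Build a profile from a per-fragment count vector aligned to the library."""
    if len(counts) != len(library):
        raise ValueError("count vector length does not match library size")
    count_map = {
        library[i].fragment_id: int(c) for i, c in enumerate(counts) if c
    }
    return InteractionProfile(
        library_ref=library_ref or f"{library.enzyme.name}:{len(library)}",
        counts=count_map,
        unassigned=0,
        total_reads=int(np.sum(counts)),
    )


def top_n(profile: InteractionProfile, n: int = DEFAULT_PEAK_N, condition: str = "") -> PeakSet:
    """Call the top-N localization peaks from a profile.

    Fragments are ranked by count descending; ties break by (chrom
    lexicographic, start ascending).  Exactly ``min(n, #fragments with
    count > 0)`` fragments are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        ((fid, c) for fid, c in profile.counts.items() if c > 0),
        key=lambda item: (-item[1],) + parse_fragment_id(item[0])[:2],
    )
    return PeakSet(condition=condition, n=n, fragments=ranked[:n])


def profile_junction_reads(
    reads: Iterable[Tuple[str, str]],
    genome: Mapping[str, str],
    library: RestrictionFragmentLibrary,
    anchor: str,
    max_mismatches: int = 0,
) -> Tuple[InteractionProfile, Dict[str, int]]:
    """Full junction-read pipeline: trim anchor, locate, assign to fragments.

    Returns the interaction profile plus a rejection tally by reason.
    Rejected reads are not part of the profile's totals (they never become
    aligned intervals).
    """
    matcher = ExactMatcher(genome)
    intervals: List[AlignedInterval] = []
    rejects: Dict[str, int] = {}
    for read_id, seq in reads:
        host = trim_viral_anchor(seq, anchor, max_mismatches)
        if isinstance(host, Rejection):
            rejects[host.reason] = rejects.get(host.reason, 0) + 1
            continue
        located = matcher.locate(host, read_id=read_id)
        if isinstance(located, Rejection):
            rejects[located.reason] = rejects.get(located.reason, 0) + 1
            continue
        intervals.append(located)
    return assign_to_fragments(intervals, library), rejects


def peakset_intersection(a: PeakSet, b: PeakSet, condition: str = "") -> PeakSet:
    """Intersect replicate peak sets by fragment id (counts from ``a``).

    Independent biological replicates are combined at the peak-set level, not
    by merging counts; the returned set keeps ``a``'s ordering and counts.
    """
    shared = b.id_set
    fragments = [(fid, c) for fid, c in a.fragments if fid in shared]
    return PeakSet(
        condition=condition or f"{a.condition}&{b.condition}",
        n=min(a.n, b.n),
        fragments=fragments,
    )
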