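"""In-silico restriction digestion of genome sequences.

A 4C-style interaction assay counts junction reads per restriction fragment, so
the exhaustive tiling of each chromosome into fragments between consecutive cut
sites is the coordinate universe for everything downstream.  This module models
the two cutters used in the V3C protocol — HindIII (primary, site ``AAGCTT``,
cut after the first base) and NlaIII (secondary, site ``CATG``, cut after the
last base) — and digests arbitrary genomes into
:class:`RestrictionFragmentLibrary` objects.

Conventions: all coordinates are 0-based half-open; the cut coordinate is
``site_start + cut_offset`` on the forward strand and overhangs are ignored
(fragments are blunt intervals — only the interval arithmetic matters for
read counting).  ``N`` bases never match a recognition site, and soft-masked
(lowercase) input is uppercased before scanning so that masking cannot change
a fragment map silently.  Chromosomes are linear; a site cannot straddle a
chromosome end.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence

import numpy as np

from .util import DNA_ALPHABET

__all__ = [
    "Enzyme",
    "HINDIII",
    "NLAIII",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "RestrictionFragment",
    "RestrictionFragmentLibrary",
    "find_sites",
    "digest",
    "parse_fragment_id",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease with a blunt-interval cut model.

    Parameters
    ----------
    name:
        Display name, e.g. ``"HindIII"``.
    recognition_site:
        Unambiguous uppercase recognition sequence over {A,C,G,T}.
    cut_offset:
        Cut coordinate relative to the site start, ``0 <= offset <= len(site)``.
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition_site:
            raise ValueError("recognition_site must be nonempty")
        bad = set(self.recognition_site) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"recognition_site must be uppercase A/C/G/T, got {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError(
                "cut_offset must lie within the recognition site "
                f"(0..{len(self.recognition_site)}), got {self.cut_offset}"
            )


HINDIII = Enzyme("HindIII", "AAGCTT", 1)
NLAIII = Enzyme("NlaIII", "CATG", 4)

BUILTIN_ENZYMES: Dict[str, Enzyme] = {e.name: e for e in (HINDIII, NLAIII)}


def get_enzyme(name: str) -> Enzyme:
    """Resolve an enzyme by name; raises naming the valid choices."""
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        valid = ", ".join(sorted(BUILTIN_ENZYMES))
        raise ValueError(f"unknown enzyme {name!r}; valid enzymes: {valid}") from None


@dataclass(frozen=True, order=True)
class RestrictionFragment:
    """One genome-tiling fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def fragment_id(self) -> str:
        """Deterministic id ``chrom:start-end``."""
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_fragment_id(fragment_id: str) -> tuple:
    """Invert :attr:`RestrictionFragment.fragment_id` -> (chrom, start, end)."""
    try:
        chrom, span = fragment_id.rsplit(":", 1)
        start_s, end_s = span.split("-")
        return chrom, int(start_s), int(end_s)
    except ValueError:
        raise ValueError(f"malformed fragment id {fragment_id!r}") from None


class RestrictionFragmentLibrary:
    """Ordered, genome-tiling set of restriction fragments.

    Fragments are sorted by (chrom, start) and, per chromosome, tile
    ``[0, chrom_length)`` exactly: the first starts at 0, the last ends at the
    chromosome length, and consecutive fragments abut.
    """

    def __init__(
        self,
        enzyme: Enzyme,
        fragments: Sequence[RestrictionFragment],
        chrom_sizes: Mapping[str, int],
        validate: bool = True,
    ) -> None:
        self.enzyme = enzyme
        self.fragments: List[RestrictionFragment] = sorted(
            fragments, key=lambda f: (f.chrom, f.start)
        )
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        self._starts_by_chrom: Dict[str, list] = {}
        self._frags_by_chrom: Dict[str, List[RestrictionFragment]] = {}
        for frag in self.fragments:
            self._starts_by_chrom.setdefault(frag.chrom, []).append(frag.start)
            self._frags_by_chrom.setdefault(frag.chrom, []).append(frag)
        self._index: Dict[str, int] = {
            f.fragment_id: i for i, f in enumerate(self.fragments)
        }
        if validate:
            self.validate()

    def validate(self) -> None:
        """Check the tiling invariant; raise ValueError on violation."""
        if set(self._frags_by_chrom) != set(self.chrom_sizes):
            raise ValueError("fragment chromosomes do not match chrom_sizes")
        for chrom, frags in self._frags_by_chrom.items():
            size = self.chrom_sizes[chrom]
            if frags[0].start != 0:
                raise ValueError(f"{chrom}: first fragment does not start at 0")
            if frags[-1].end != size:
                raise ValueError(f"{chrom}: last fragment does not end at {size}")
            for prev, cur in zip(frags, frags[1:]):
                if prev.end != cur.start:
                    raise ValueError(
                        f"{chrom}: gap/overlap between {prev.fragment_id} "
                        f"and {cur.fragment_id}"
                    )

    @property
    def ids(self) -> List[str]:
        return [f.fragment_id for f in self.fragments]

    def index_of(self, fragment_id: str) -> int:
        return self._index[fragment_id]

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self._index

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[RestrictionFragment]:
        return iter(self.fragments)

    def __getitem__(self, i: int) -> RestrictionFragment:
        return self.fragments[i]

    def fragment_at(self, chrom: str, pos: int) -> Optional[RestrictionFragment]:
        """Fragment containing base ``pos`` on ``chrom``, or None."""
        frags = self._frags_by_chrom.get(chrom)
        if frags is None:
            return None
        if not 0 <= pos < self.chrom_sizes[chrom]:
            return None
        i = bisect.bisect_right(self._starts_by_chrom[chrom], pos) - 1
        return frags[i]


def find_sites(seq: str, enzyme: Enzyme) -> List[int]:
    """All start positions of the recognition site in ``seq``, ascending.

    Matching is case-insensitive and exact; ``N`` never matches.  Overlapping
    occurrences are all reported (e.g. the CATG sites of ``CATGCATG`` are at
    0 and 4).  An empty sequence yields an empty list.
    """
    s = seq.upper()
    site = enzyme.recognition_site
    out: List[int] = []
    i = s.find(site)
    while i != -1:
        out.append(i)
        i = s.find(site, i + 1)
    return out


def digest(genome: Mapping[str, str], enzyme) -> RestrictionFragmentLibrary:
    """Digest a genome into its restriction-fragment library.

    Per chromosome the cut coordinates are ``site_start + cut_offset`` for
    every recognition-site occurrence; fragments are the intervals between 0,
    the sorted cuts, and the chromosome length.  Cuts falling exactly on a
    chromosome boundary are dropped (no empty fragments).

    Parameters
    ----------
    genome:
        Mapping chrom -> DNA string; every chromosome must be nonempty.
    enzyme:
        An :class:`Enzyme` or the name of a built-in one.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    fragments: List[RestrictionFragment] = []
    chrom_sizes: Dict[str, int] = {}
    for chrom in sorted(genome):
        seq = genome[chrom]
        if not seq:
            raise ValueError(f"chromosome {chrom!r} is empty")
        length = len(seq)
        chrom_sizes[chrom] = length
        cuts = sorted(
            {p + enzyme.cut_offset for p in find_sites(seq, enzyme)}
            - {0, length}
        )
        bounds = [0, *cuts, length]
        for start, end in zip(bounds, bounds[1:]):
            fragments.append(RestrictionFragment(chrom, start, end))
    return RestrictionFragmentLibrary(enzyme, fragments, chrom_sizes)
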