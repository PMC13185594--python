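"""Readers and writers shared by the pipeline.

All coordinates are 0-based half-open internally; every writer emits the
standard its format defines.  BED is the single interchange format between
stages (fragments, peaks, sites) and bedGraph carries per-fragment signals,
matching the BEDtools/deepTools ecosystem this pipeline mirrors.  FASTA goes
through Biopython, SAM through pysam (mapped, primary, non-supplementary
records only).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import RestrictionFragmentLibrary

logger = logging.getLogger("v3cseq")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_library_bed",
    "read_genome_sizes",
    "write_genome_sizes",
    "read_sam_intervals",
    "write_bedgraph",
    "write_fastq",
    "write_profile_tsv",
    "read_profile_tsv",
    "file_digest",
]

BedInterval = Tuple[str, int, int, str]


def read_fasta(path) -> Dict[str, str]:
    """Read a (multi-record) FASTA into a chrom -> sequence mapping.

    Duplicate record ids are an error; sequence case is preserved.
    """
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq)
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> List[BedInterval]:
    """Read BED (3+ columns) as (chrom, start, end, name) tuples.

    Coordinates must already be 0-based half-open, the convention BED defines;
    malformed records raise with their line number.
    """
    out: List[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r},"
                    f" {fields[2]!r}"
                ) from None
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}); BED is "
                    "0-based half-open with start < end (1-based inclusive input "
                    "is not accepted)"
                )
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            out.append((chrom, start, end, name))
    return out


def write_bed(intervals: Iterable[Sequence], path) -> None:
    """Write BED6 rows (chrom, start, end, name, 0, '.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else f"{chrom}:{start}-{end}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")


def write_library_bed(library: RestrictionFragmentLibrary, path) -> None:
    write_bed(
        ((f.chrom, f.start, f.end, f.fragment_id) for f in library.fragments), path
    )


def read_genome_sizes(path) -> Dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need chrom<TAB>length")
            chrom = fields[0]
            if chrom in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            length = int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length}")
            sizes[chrom] = length
    return sizes


def write_genome_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_sam_intervals(path):
    """Read a SAM file into aligned intervals, keeping primary alignments only.

    Unmapped, secondary and supplementary records are skipped and tallied in
    the returned skip log (a reason -> count mapping).

    Returns
    -------
    (intervals, skipped) where intervals is a list of
    :class:`~v3cseq.fragments.AlignedInterval`.
    """
    from .fragments import AlignedInterval  # local import to avoid a cycle

    intervals: List = []
    skipped: Dict[str, int] = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            intervals.append(
                AlignedInterval(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    read_id=rec.query_name,
                    mapq=rec.mapping_quality,
                )
            )
    if any(skipped.values()):
        logger.info("read_sam_intervals(%s): skipped %s", path, skipped)
    return intervals, skipped


def write_bedgraph(profile, library: RestrictionFragmentLibrary, path) -> None:
    """Write per-fragment counts as bedGraph (nonzero fragments only)."""
    with open(path, "w") as fh:
        for frag in library.fragments:
            count = profile.counts.get(frag.fragment_id, 0)
            if count:
                fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{count}\n")


def write_fastq(reads: Iterable[Tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_profile_tsv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library={profile.library_ref}\n")
        fh.write(f"#unassigned={profile.unassigned}\n")
        fh.write(f"#total_reads={profile.total_reads}\n")
        fh.write("fragment_id\tcount\n")
        for fid in sorted(profile.counts):
            fh.write(f"{fid}\t{profile.counts[fid]}\n")


def read_profile_tsv(path):
    from .fragments import InteractionProfile

    meta: Dict[str, str] = {}
    counts: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            if line.startswith("fragment_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: need fragment_id<TAB>count")
            counts[fields[0]] = int(fields[1])
    return InteractionProfile(
        library_ref=meta.get("library", ""),
        counts=counts,
        unassigned=int(meta.get("unassigned", 0)),
        total_reads=int(meta.get("total_reads", sum(counts.values()))),
    )


def file_digest(path) -> str:
    """Short sha256 digest of a file, for run logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
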