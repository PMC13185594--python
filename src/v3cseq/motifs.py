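"""PWM motif scanning, shuffle-based enrichment, and site-centered coverage.

The motif of interest is the KLF4 consensus binding element AGGGGTGGAGTC,
shipped as a one-hot position frequency matrix; arbitrary JASPAR-format PFMs
are accepted as input.  Scanning scores every window on both strands with
log2-odds against a background model and reports hits above a min-max scaled
relative score (default 0.8, the common JASPAR-scan convention).  Enrichment
of a motif in a region set is assessed against a composition-preserving
mononucleotide shuffle null with an add-one empirical p-value.  Site-centered
coverage matrices (a deepTools "reference-point" analogue) average a signal
in fixed-size bins around anchor points, e.g. 10 kb windows around promoters
or 100 kb bins around ChIP peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .util import revcomp

__all__ = [
    "PWM",
    "MotifHit",
    "EnrichmentResult",
    "SiteMatrix",
    "pfm_to_pwm",
    "read_jaspar_pfm",
    "scan",
    "shuffle_enrichment",
    "site_matrix",
    "coverage_from_bedgraph",
    "KLF4_CONSENSUS",
    "klf4_consensus_pfm",
    "klf4_pwm",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: KLF4 consensus binding element; its dimer is the insert used to augment
#: recombinant AAV2 vectors.
KLF4_CONSENSUS = "AGGGGTGGAGTC"

_REL_EPS = 1e-9  # float tolerance when comparing rel_score to the threshold


@dataclass
class PWM:
    """Position weight matrix with a background model.

    ``probs`` has one row per motif position and columns A, C, G, T, each row
    summing to 1 with strictly positive entries (guaranteed by the pseudocount
    applied at construction).
    """

    name: str
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a (width, 4) matrix")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("each PWM row must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be > 0 (use a pseudocount)")
        if not np.isclose(self.background.sum(), 1.0) or np.any(self.background <= 0):
            raise ValueError("background must be a positive 4-vector summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(prob / background), shape (width, 4)."""
        return np.log2(self.probs / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; coordinates always refer to the forward strand."""

    seq_id: str
    start: int
    strand: str
    score: float
    rel_score: float


@dataclass
class EnrichmentResult:
    """Observed motif hit count against a shuffle null."""

    observed_hits: int
    shuffled_hits: List[int]
    p_value: float
    n_shuffles: int
    seed: int


@dataclass
class SiteMatrix:
    """Region x bin matrix of mean coverage around anchor points.

    Rows are ordered by descending row sum (``row_order`` maps back to the
    input site order); columns span ``[-window_bp, +window_bp)`` in
    ``bin_size_bp`` steps.
    """

    values: np.ndarray
    bin_size_bp: int
    window_bp: int
    sites: List[Tuple[str, int]]
    row_order: List[int]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_offsets(self) -> np.ndarray:
        """Start offset of each bin relative to the anchor."""
        return np.arange(-self.window_bp, self.window_bp, self.bin_size_bp)

    def to_tsv(self, path) -> None:
        header = "site\t" + "\t".join(str(o) for o in self.bin_offsets)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for (chrom, anchor), row in zip(self.sites, self.values):
                cells = "\t".join(f"{v:.6g}" for v in row)
                fh.write(f"{chrom}:{anchor}\t{cells}\n")


def pfm_to_pwm(
    counts: np.ndarray,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.8,
    name: str = "",
) -> PWM:
    """Convert a position frequency (count) matrix to a PWM.

    ``probs = (counts + pseudocount * background) / (row_sum + pseudocount)``;
    log-odds are derived lazily as log2(prob / background).  Rows of all-zero
    counts are an error.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be a (width, 4) matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every PFM row needs at least one nonzero count")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    probs = (counts + pseudocount * bg[None, :]) / (row_sums + pseudocount)[:, None]
    return PWM(name=name, probs=probs, background=bg, pseudocount=pseudocount)


def read_jaspar_pfm(path, background=None, pseudocount: float = 0.8) -> PWM:
    """Read a JASPAR-format PFM file (">ID NAME" + 4 bracketed count rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in BASES], dtype=float).T
    name = f"{motif.matrix_id} {motif.name}".strip() if motif.matrix_id else motif.name
    return pfm_to_pwm(counts, background=background, pseudocount=pseudocount, name=name)


def klf4_consensus_pfm() -> np.ndarray:
    """One-hot PFM of the KLF4 consensus element AGGGGTGGAGTC."""
    counts = np.zeros((len(KLF4_CONSENSUS), 4))
    for i, base in enumerate(KLF4_CONSENSUS):
        counts[i, _BASE_INDEX[base]] = 1.0
    return counts


def klf4_pwm(pseudocount: float = 0.8) -> PWM:
    return pfm_to_pwm(klf4_consensus_pfm(), pseudocount=pseudocount, name="KLF4")


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes 0..3 (A,C,G,T); anything else to 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    width = log_odds.shape[0]
    # non-ACGT bases get a large negative score so their windows never pass
    lo = np.hstack([log_odds, np.full((width, 1), -1e9)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    return lo[np.arange(width)[None, :], windows].sum(axis=1)


def scan(
    seq: str,
    pwm: PWM,
    rel_threshold: float = 0.8,
    seq_id: str = "",
) -> List[MotifHit]:
    """Scan both strands of a sequence for PWM hits.

    A window is a hit when its min-max scaled log-odds score
    ``(score - min) / (max - min)`` reaches ``rel_threshold``.  Reverse-strand
    hit coordinates refer to the forward strand; all (including overlapping)
    hits are reported, sorted by position.  Sequences shorter than the motif
    yield no hits.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    if len(seq) < pwm.width:
        return []
    codes = _encode(seq)
    span = pwm.max_score - pwm.min_score
    hits: List[MotifHit] = []
    for strand, matrix in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        scores = _window_scores(codes, matrix)
        rel = (scores - pwm.min_score) / span
        for pos in np.nonzero(rel >= rel_threshold - _REL_EPS)[0]:
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=int(pos),
                    strand=strand,
                    score=float(scores[pos]),
                    rel_score=float(min(max(rel[pos], 0.0), 1.0)),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return rng.permutation(chars).tobytes().decode("ascii")


def shuffle_enrichment(
    regions: Sequence[str],
    pwm: PWM,
    rel_threshold: float = 0.8,
    n_shuffles: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Motif enrichment in a region set against a mononucleotide-shuffle null.

    The observed statistic is the total hit count over all regions; each null
    draw shuffles every region independently (preserving its exact base
    composition) and rescans.  p-value uses the add-one rule.
    """
    if not regions:
        raise ValueError("region list must be nonempty")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = sum(len(scan(r, pwm, rel_threshold)) for r in regions)
    rng = np.random.default_rng(seed)
    shuffled: List[int] = []
    for _ in range(n_shuffles):
        total = sum(
            len(scan(_mononucleotide_shuffle(r, rng), pwm, rel_threshold))
            for r in regions
        )
        shuffled.append(total)
    exceed = sum(1 for v in shuffled if v >= observed)
    p_value = (1 + exceed) / (1 + n_shuffles)
    return EnrichmentResult(
        observed_hits=observed,
        shuffled_hits=shuffled,
        p_value=p_value,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def coverage_from_bedgraph(
    records: Sequence[Tuple[str, int, int, float]],
    chrom_sizes: Mapping[str, int],
) -> Dict[str, np.ndarray]:
    """Expand bedGraph records into dense per-bp arrays."""
    cov = {c: np.zeros(L, dtype=float) for c, L in chrom_sizes.items()}
    for chrom, start, end, value in records:
        if chrom not in cov:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom_sizes")
        cov[chrom][start:end] += value
    return cov


def site_matrix(
    sites: Sequence,
    coverage: Mapping[str, np.ndarray],
    window_bp: int,
    bin_size_bp: int,
) -> SiteMatrix:
    """Mean coverage in fixed bins around anchor points.

    ``sites`` are (chrom, anchor) points or (chrom, start, end) intervals
    (anchored at their midpoint).  Each row covers
    ``[anchor - window_bp, anchor + window_bp)``; spans outside the chromosome
    contribute 0.  Rows are sorted by descending total signal.
    """
    if not sites:
        raise ValueError("site list must be nonempty")
    if window_bp <= 0 or bin_size_bp <= 0:
        raise ValueError("window_bp and bin_size_bp must be positive")
    if window_bp % bin_size_bp != 0:
        raise ValueError("window_bp must be divisible by bin_size_bp")
    anchors: List[Tuple[str, int]] = []
    for site in sites:
        if len(site) == 2:
            anchors.append((site[0], int(site[1])))
        elif len(site) == 3:
            anchors.append((site[0], (int(site[1]) + int(site[2])) // 2))
        else:
            raise ValueError("sites must be (chrom, pos) or (chrom, start, end)")
    n_bins = 2 * window_bp // bin_size_bp
    values = np.zeros((len(anchors), n_bins))
    for i, (chrom, anchor) in enumerate(anchors):
        track = coverage.get(chrom)
        if track is None:
            continue  # off-library chromosome: all bins stay 0
        window = np.zeros(2 * window_bp)
        lo, hi = anchor - window_bp, anchor + window_bp
        src_lo, src_hi = max(lo, 0), min(hi, len(track))
        if src_lo < src_hi:
            window[src_lo - lo : src_hi - lo] = track[src_lo:src_hi]
        values[i] = window.reshape(n_bins, bin_size_bp).mean(axis=1)
    order = list(np.argsort(-values.sum(axis=1), kind="stable"))
    return SiteMatrix(
        values=values[order],
        bin_size_bp=bin_size_bp,
        window_bp=window_bp,
        sites=[anchors[i] for i in order],
        row_order=[int(i) for i in order],
    )
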