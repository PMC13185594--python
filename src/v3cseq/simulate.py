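"""Ground-truthed synthetic inputs for the V3C analysis pipeline.

Three generators emulate the statistical structure the analysis assumes:

* a multi-chromosome host genome of i.i.d. bases at a chosen GC content,
  carrying naturally occurring HindIII/NlaIII sites and optionally planted
  KLF4 consensus motifs at known positions;
* chimeric virus-host junction reads (viral anchor + host segment) whose
  host-side fragment counts are uniform background plus a fold enrichment at
  planted interaction fragments — the ground truth for peak-recovery tests;
* two-channel micro-irradiation stripe images: a Gaussian-profile damage
  stripe plus virus foci, a chosen fraction of which are centered inside the
  stripe.

Per-fragment read sampling is a single categorical draw (probability
proportional to background weight, times the fold enrichment for planted
fragments), which makes marginal fragment counts multinomial — approximately
independent Poissons around the stated means at these scales.  Sampling
weights are independent of fragment length by default (``length_weighted``
flag available), since peak calling uses raw per-fragment counts.  All
generators are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .digest import RestrictionFragmentLibrary
from .stripes import StripeROI
from .util import revcomp

__all__ = [
    "SyntheticGenomeConfig",
    "InteractionTruth",
    "JunctionReadSet",
    "SyntheticStripeConfig",
    "StripeImage",
    "simulate_genome",
    "simulate_junction_reads",
    "simulate_fragment_counts",
    "simulate_stripe_image",
    "default_genome_config",
    "choose_planted_fragments",
    "DEFAULT_ANCHOR",
    "DEFAULT_READ_LEN",
]

#: wtAAV2 HindIII nested inverse-PCR primer: the viral-side anchor of a
#: junction read.
DEFAULT_ANCHOR = "CATCGACGTCAGACGCGG"
DEFAULT_READ_LEN = 50

_BYTES_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeConfig:
    """Recipe for a toy host genome standing in for a reference assembly.

    Defaults (four 800 kb chromosomes, GC 0.41) give a HindIII site density
    near 1/3.1 kb and therefore a library of about a thousand fragments —
    desk-scale but statistically meaningful for peak recovery.
    """

    chrom_lengths: Dict[str, int]
    gc_fraction: float = 0.41
    planted_motifs: List[Tuple[str, int, str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, pos, motif, strand in self.planted_motifs:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"planted motif on unknown chromosome {chrom!r}")
            if strand not in "+-":
                raise ValueError(f"motif strand must be + or -, got {strand!r}")
            if pos < 0 or pos + len(motif) > self.chrom_lengths[chrom]:
                raise ValueError(
                    f"motif at {chrom}:{pos} (len {len(motif)}) falls outside "
                    f"the {self.chrom_lengths[chrom]} bp chromosome"
                )
            spans.setdefault(chrom, []).append((pos, pos + len(motif)))
        for chrom, intervals in spans.items():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"planted motifs overlap on {chrom} at {s2} < {e1}"
                    )


def default_genome_config(
    seed: int = 0,
    planted_motifs: Optional[Sequence[Tuple[str, int, str, str]]] = None,
) -> SyntheticGenomeConfig:
    """The package's standard toy-genome conditions: 4 chroms x 800 kb, GC 0.41."""
    return SyntheticGenomeConfig(
        chrom_lengths={f"chr{i}": 800_000 for i in range(1, 5)},
        gc_fraction=0.41,
        planted_motifs=list(planted_motifs or []),
        seed=seed,
    )


def simulate_genome(cfg: SyntheticGenomeConfig) -> Dict[str, str]:
    """Draw the genome: i.i.d. bases, then planted motifs overwrite in place.

    P(G) = P(C) = gc_fraction / 2; motifs on the minus strand are planted as
    their reverse complement.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    at = (1 - cfg.gc_fraction) / 2
    gc = cfg.gc_fraction / 2
    probs = np.array([at, gc, gc, at])
    genome: Dict[str, str] = {}
    for chrom in sorted(cfg.chrom_lengths):
        codes = rng.choice(4, size=cfg.chrom_lengths[chrom], p=probs)
        genome[chrom] = _BYTES_ACGT[codes].tobytes().decode("ascii")
    for chrom, pos, motif, strand in cfg.planted_motifs:
        insert = motif.upper() if strand == "+" else revcomp(motif.upper())
        seq = genome[chrom]
        genome[chrom] = seq[:pos] + insert + seq[pos + len(insert):]
    return genome


@dataclass
class InteractionTruth:
    """Ground truth of a simulated interaction landscape."""

    planted_fragment_ids: frozenset
    fold_enrichment: float
    background_mean: float

    def __post_init__(self) -> None:
        self.planted_fragment_ids = frozenset(self.planted_fragment_ids)
        if self.fold_enrichment < 1:
            raise ValueError("fold_enrichment must be >= 1")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")


@dataclass
class JunctionReadSet:
    """Simulated junction reads plus the per-read source-fragment truth."""

    reads: List[Tuple[str, str]]
    truth: Dict[str, str]


def choose_planted_fragments(
    library: RestrictionFragmentLibrary,
    n_planted: int,
    seed: int = 0,
    min_length: int = 100,
) -> frozenset:
    """Pick planted interaction fragments at random (length >= min_length,
    so junction reads from them carry full-length host segments)."""
    eligible = [f.fragment_id for f in library.fragments if f.length >= min_length]
    if len(eligible) < n_planted:
        raise ValueError(
            f"only {len(eligible)} fragments of >= {min_length} bp available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_planted, replace=False)
    return frozenset(eligible[i] for i in chosen)


def _fragment_weights(
    library: RestrictionFragmentLibrary,
    truth: InteractionTruth,
    length_weighted: bool,
) -> np.ndarray:
    missing = truth.planted_fragment_ids - set(library.ids)
    if missing:
        raise ValueError(
            f"planted fragments not in library: {sorted(missing)[:3]} ..."
        )
    weights = np.full(len(library), truth.background_mean, dtype=float)
    for fid in truth.planted_fragment_ids:
        weights[library.index_of(fid)] *= truth.fold_enrichment
    if length_weighted:
        weights *= np.array([f.length for f in library.fragments], dtype=float)
    return weights


def _sample_fragment_indices(
    library: RestrictionFragmentLibrary,
    truth: InteractionTruth,
    n_reads: int,
    rng: np.random.Generator,
    length_weighted: bool,
) -> np.ndarray:
    weights = _fragment_weights(library, truth, length_weighted)
    return rng.choice(len(library), size=n_reads, p=weights / weights.sum())


def simulate_fragment_counts(
    library: RestrictionFragmentLibrary,
    truth: InteractionTruth,
    n_reads: int,
    seed: int = 0,
    length_weighted: bool = False,
) -> np.ndarray:
    """Per-fragment read counts under the interaction truth (no sequences).

    The same categorical draw as :func:`simulate_junction_reads`, tallied
    directly — the cheap path for large seed sweeps.
    """
    rng = np.random.default_rng(seed)
    idx = _sample_fragment_indices(library, truth, n_reads, rng, length_weighted)
    return np.bincount(idx, minlength=len(library))


def simulate_junction_reads(
    genome: Mapping[str, str],
    library: RestrictionFragmentLibrary,
    truth: InteractionTruth,
    n_reads: int,
    anchor: str = DEFAULT_ANCHOR,
    read_len: int = DEFAULT_READ_LEN,
    seed: int = 0,
    length_weighted: bool = False,
) -> JunctionReadSet:
    """Simulate chimeric virus-host junction reads.

    Every read is ``anchor + host segment``, the host segment being the first
    ``read_len - len(anchor)`` bases of its source fragment (truncated at the
    fragment end).  Source fragments are drawn with probability proportional
    to ``background_mean`` (times ``fold_enrichment`` when planted).  Reads
    carry the forward-strand fragment sequence; ligation strand is not
    modeled, since downstream counting is strand-agnostic.
    """
    if read_len <= len(anchor):
        raise ValueError("read_len must exceed the anchor length")
    rng = np.random.default_rng(seed)
    idx = _sample_fragment_indices(library, truth, n_reads, rng, length_weighted)
    seg_len = read_len - len(anchor)
    reads: List[Tuple[str, str]] = []
    truth_map: Dict[str, str] = {}
    for i, frag_i in enumerate(idx):
        frag = library[int(frag_i)]
        host = genome[frag.chrom][frag.start : min(frag.end, frag.start + seg_len)]
        read_id = f"read{i:07d}"
        reads.append((read_id, anchor + host))
        truth_map[read_id] = frag.fragment_id
    return JunctionReadSet(reads=reads, truth=truth_map)


@dataclass
class SyntheticStripeConfig:
    """Recipe for a two-channel micro-irradiation stripe image.

    Channel 1 (damage) is a Gaussian-profile stripe along a horizontal axis;
    channel 2 (virus) is ``focus_count`` Gaussian foci, of which a
    ``colocalized_fraction`` are centered inside the stripe band and the rest
    outside it.  Amplitudes are in arbitrary intensity units.
    """

    image_shape: Tuple[int, int] = (200, 200)
    stripe_axis_length_px: int = 120
    stripe_width_px: int = 9
    damage_amplitude: float = 100.0
    focus_count: int = 20
    colocalized_fraction: float = 0.5
    noise_sd: float = 2.0
    focus_amplitude: float = 80.0
    focus_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if self.stripe_width_px % 2 == 0 or self.stripe_width_px < 1:
            raise ValueError("stripe_width_px must be a positive odd integer")
        if self.stripe_axis_length_px > cols or self.stripe_width_px > rows:
            raise ValueError("stripe does not fit inside the image")
        if self.focus_count < 0:
            raise ValueError("focus_count must be >= 0")
        if not 0 <= self.colocalized_fraction <= 1:
            raise ValueError("colocalized_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class StripeImage:
    """Simulated two-channel image plus its ground truth."""

    damage: np.ndarray
    virus: np.ndarray
    roi: StripeROI
    focus_centers: List[Tuple[int, int]]
    colocalized: List[bool]


def _stripe_geometry(cfg: SyntheticStripeConfig):
    rows, cols = cfg.image_shape
    row0 = rows // 2
    col0 = (cols - cfg.stripe_axis_length_px) // 2
    return row0, col0, col0 + cfg.stripe_axis_length_px


def simulate_stripe_image(cfg: SyntheticStripeConfig) -> StripeImage:
    """Render the two channels and record the stripe ROI and focus truth."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.image_shape
    row0, col_lo, col_hi = _stripe_geometry(cfg)
    half = cfg.stripe_width_px // 2
    sigma = max(cfg.stripe_width_px / 4.0, 0.5)

    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    in_cols = (cc >= col_lo) & (cc < col_hi)
    damage = cfg.damage_amplitude * np.exp(-((rr - row0) ** 2) / (2 * sigma**2)) * in_cols

    in_band = (np.abs(rr - row0) <= half) & in_cols  # the truth stripe mask
    n_coloc = int(round(cfg.colocalized_fraction * cfg.focus_count))
    centers: List[Tuple[int, int]] = []
    flags: List[bool] = []
    for _ in range(n_coloc):
        r = row0 + int(rng.integers(-half, half + 1))
        c = int(rng.integers(col_lo, col_hi))
        centers.append((r, c))
        flags.append(True)
    margin = half + int(np.ceil(3 * cfg.focus_sigma_px))
    for _ in range(cfg.focus_count - n_coloc):
        for _attempt in range(1000):
            r = int(rng.integers(0, rows))
            c = int(rng.integers(0, cols))
            outside = abs(r - row0) > margin or not (
                col_lo - margin <= c < col_hi + margin
            )
            if outside:
                break
        else:
            raise RuntimeError("could not place a focus outside the stripe")
        centers.append((r, c))
        flags.append(False)

    virus = np.zeros((rows, cols))
    two_s2 = 2 * cfg.focus_sigma_px**2
    for r, c in centers:
        virus += cfg.focus_amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / two_s2
        )

    if cfg.noise_sd > 0:
        damage = damage + rng.normal(0, cfg.noise_sd, size=damage.shape)
        virus = virus + rng.normal(0, cfg.noise_sd, size=virus.shape)
    damage = np.clip(damage, 0, None)
    virus = np.clip(virus, 0, None)

    roi = StripeROI(
        image_id=f"synthetic-seed{cfg.seed}",
        axis=[(row0, c) for c in range(col_lo, col_hi)],
        width_px=cfg.stripe_width_px,
        length_microns=10.0,
    )
    return StripeImage(
        damage=damage, virus=virus, roi=roi, focus_centers=centers, colocalized=flags
    )
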