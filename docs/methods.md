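# Methods notes

This note records the models behind each stage, the parameter choices that
matter, and what the synthetic benchmarks do and do not demonstrate.

## Restriction-fragment model

Digestion is purely positional: a cut occurs at `site_start + cut_offset` on
the forward strand at every exact occurrence of the recognition site
(HindIII `AAGCTT`, offset 1; NlaIII `CATG`, offset 4), and fragments are the
blunt intervals between consecutive cuts. Sticky-end overhangs are ignored
because only interval arithmetic matters for read counting. `N` bases never
match a site and lowercase (soft-masked) sequence is uppercased before
scanning, so masking cannot silently change a fragment map. Chromosomes are
linear; no circular-genome mode exists because the fragment library is only
ever built for the host. No minimum fragment size is enforced: short
fragments stay in the universe and simply tend to collect unlocatable reads
(see below).

## Synthetic study conditions

The generators define fixed study conditions rather than free dials:

* **Host genome** — 4 chromosomes × 800 kb of i.i.d. bases at GC 0.41
  (human-like). At this composition the HindIII site probability is
  0.295⁴·0.205² ≈ 1/3136 bp, so the default genome digests into ≈1,000
  fragments — about a thousand-fragment universe in which 10 planted
  fragments are a 1% minority, small enough to run at a desk and large
  enough for rank statistics to be meaningful. Planted motifs overwrite the
  random sequence at fixed positions (reverse-complemented on the minus
  strand) and must not overlap each other.
* **Junction reads** — every read is `anchor + host segment`, the anchor
  being the viral-side nested inverse-PCR primer (`CATCGACGTCAGACGCGG`) and
  the host segment the first `read_len − len(anchor)` bases of the source
  fragment (50 bp reads → 32 bp segments), truncated at the fragment end.
  Source fragments are drawn i.i.d. with weight `background_mean` (default
  5), multiplied by `fold_enrichment` (default 20) for the 10 planted
  fragments. A single categorical draw makes the per-fragment counts
  multinomial — effectively independent Poissons around their means at these
  scales, the natural first model for count noise in the absence of
  information about real per-fragment dispersion. Weights are
  length-independent by default (`length_weighted=True` available) because
  peak calling uses raw per-fragment counts, not density.
  `simulate_fragment_counts` performs the identical draw without
  materializing sequences; seed sweeps use it, while the full
  read→trim→locate→assign path is exercised at fixed seeds.
* **Stripe images** — 200×200 px, a horizontal damage stripe of 120 px
  length and 9 px width (Gaussian cross-section, amplitude 100), 20 viral
  foci of amplitude 80 and σ = 2 px, additive Gaussian noise σ = 2, and a
  configurable colocalized fraction: that share of focus centers is placed
  uniformly inside the stripe band, the rest uniformly outside it with a
  margin of half-width + 3σ so their tails do not leak into the stripe.

What the generators deliberately do **not** emulate: sequencing errors, PCR
duplicates, mappability structure, chromatin-driven background
heterogeneity, diploid variation, microscope PSF anisotropy, uneven
illumination, or cell-to-cell variability in stripe geometry. Passing the
synthetic benchmarks therefore shows the *computational* pipeline is correct
and well-calibrated under its stated noise model, not that real libraries
would reach the same recovery rates.

## Read location and fragment assignment

The exact-match locator is a stand-in for an external aligner, usable only
on synthetic data: a host segment is accepted when it occurs exactly once in
the genome, and rejected as `too_short` (< 20 bp), `absent`, or `ambiguous`
otherwise. Bulk location memoizes per unique segment, since simulated reads
have at most one distinct segment per fragment.

Each aligned interval is assigned to the fragment containing its **5′-most
base**: the junction-proximal end of a 4C-style read is its informative
coordinate, so midpoint or max-overlap rules would blur boundary-spanning
reads. Counts are raw (no length normalization), the MAPQ filter defaults to
0 (keep everything), and no viewpoint exclusion zone is applied — the
viewpoint here is episomal/viral, not a chromosomal locus with
self-ligation neighbors. Peak calling takes the top 150 fragments by count,
breaking ties deterministically by (chrom, start). Replicates are combined
by intersecting peak sets, never by merging counts.

## Overlap statistics

The Jaccard index is computed on merged interval sets in bp; two empty sets
are an error rather than 0. "Shared" between two peak sets on the same
fragment universe means identical fragment id; bp-overlap mode (≥ 1 bp, the
usual interval-intersection default) serves cross-universe comparisons. The
permutation null places `n` intervals of the partner set's mean size
independently and uniformly (chromosome chosen ∝ eligible length;
self-overlap allowed; no blacklist, since none is defined for the synthetic
genome), and the add-one empirical p-value keeps p > 0 — standard
permutation-test practice. Placement is global rather than per-chromosome
matched; on a genome with exchangeable chromosomes the two are equivalent.

At desk scale the null is heavy: 150 × 5 kb = 750 kb of random intervals on
a 3.2 Mb genome overlaps any top-150 set (~470 kb) substantially, so the
permutation test has modest power for weakly overlapping conditions. This
is inherent to the miniature genome, not to the statistic.

## Motif scanning

PFMs become PWMs via `probs = (counts + pseudocount·background) /
(row_sum + pseudocount)` (default pseudocount 0.8, uniform background);
scores are log₂(prob/background) summed over the window, reported alongside
the min–max scaled relative score. The default hit threshold is relative
score 0.8, the common JASPAR-scan convention. Both strands are scanned with
reverse-strand coordinates mapped to the forward strand, and overlapping
hits are all reported — a dimer insert must yield two hits. Windows
containing non-ACGT characters never pass. Enrichment uses a
per-sequence mononucleotide shuffle (exact composition preserved);
dinucleotide structure is not preserved, which is adequate for a 12-mer
consensus and keeps the null seedable and simple. Site-centered matrices
average coverage in `(2·window)/bin` bins per anchor (interval anchors use
the midpoint, the reference-point convention), zero-fill out-of-chromosome
spans, and sort rows by descending total.

## Stripe quantification

Co-localized intensity is defined as the viral channel multiplied by the
damage-positive indicator (Otsu by default; a constant image directs the
user to a fixed threshold). Intensity is averaged over 11 px perpendicular
to the ROI axis by default — the protocol fixes stripe length (10 µm) but
not width. Binning partitions the axis profile into 75 (or 90) spans as
equal as possible, remainder pixels going to the leading bins; bin means
preserve the profile mean exactly when the length divides evenly.
Aggregation reports per-bin mean ± SEM (sample SD/√n) over cells, warns
below the conventional 10 cells, and reports SEM = 0 for a single cell.
Intensities are neither background-subtracted nor per-cell normalized;
a per-cell normalization can be applied upstream if desired.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 100 random sequences up to
10 kb for the digestion oracle; 100,000 reads on the ~1,000-fragment genome,
once through the full read pipeline and across a 100-seed count-level sweep,
for planted recovery; 200 runs × 99 permutations for null calibration;
100 random sequences for strand symmetry; and 100 synthetic image pairs for
stripe discrimination. These sizes give binomial error bars of a few percent
on every rate while keeping the whole suite fast on a single CPU.

## Known limitations

* The exact-match locator cannot handle mismatches, indels or multimapping
  beyond rejection; real libraries need a true aligner upstream.
* Poisson/multinomial count noise understates the overdispersion of real 4C
  libraries; recovery rates on real data will be lower at equal fold
  enrichment.
* The permutation null ignores mappability and chromatin accessibility
  biases that shape real random-interval overlap.
* PWM scanning reports relative-score hits, not dynamic-programming
  p-values; scores are not calibrated across motifs of different widths.
* Stripe ROIs are polylines with integer-pixel perpendicular sampling;
  strongly curved ROIs sample slightly unevenly.
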