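"""PWM construction, strand-aware scanning, shuffle nulls, site matrices."""

import numpy as np
import pytest

import v3cseq as v
from v3cseq.motifs import (
    klf4_consensus_pfm,
    coverage_from_bedgraph,
    _mononucleotide_shuffle,
)
from v3cseq.util import revcomp


class TestPfmToPwm:
    def test_one_hot_consensus_round_trip(self, klf4_pwm):
        assert klf4_pwm.consensus == "AGGGGTGGAGTC"

    def test_uniform_row_gives_zero_log_odds(self):
        counts = np.vstack([np.ones(4)] * 4)
        pwm = v.pfm_to_pwm(counts)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_pseudocount_changes_scores_not_consensus(self):
        counts = klf4_consensus_pfm()
        small = v.pfm_to_pwm(counts, pseudocount=0.1)
        large = v.pfm_to_pwm(counts, pseudocount=1.0)
        assert small.consensus == large.consensus == "AGGGGTGGAGTC"
        assert not np.allclose(small.log_odds, large.log_odds)

    def test_zero_row_rejected(self):
        counts = klf4_consensus_pfm()
        counts[3] = 0
        with pytest.raises(ValueError):
            v.pfm_to_pwm(counts)

    def test_row_normalization(self):
        counts = np.array([[3, 1, 0, 0], [0, 0, 5, 5], [1, 1, 1, 1], [0, 9, 0, 1]])
        pwm = v.pfm_to_pwm(counts, pseudocount=0.5)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert np.all(pwm.probs > 0)


class TestScan:
    def test_dimer_insert_yields_exactly_two_hits(self, klf4_pwm):
        hits = v.scan(v.KLF4_CONSENSUS * 2, klf4_pwm, rel_threshold=1.0)
        forward = [h for h in hits if h.strand == "+"]
        assert [h.start for h in forward] == [0, 12]
        assert all(h.rel_score == pytest.approx(1.0) for h in forward)

    def test_poly_a_has_no_hits(self, klf4_pwm):
        assert v.scan("A" * 200, klf4_pwm, rel_threshold=0.8) == []

    def test_sequence_shorter_than_motif_is_empty(self, klf4_pwm):
        assert v.scan("ACGT", klf4_pwm) == []

    def test_minus_strand_hit_reported_in_forward_coordinates(self, klf4_pwm):
        seq = "T" * 30 + revcomp(v.KLF4_CONSENSUS) + "T" * 30
        hits = v.scan(seq, klf4_pwm, rel_threshold=1.0)
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].start == 30

    def test_consensus_attains_maximal_relative_score(self, klf4_pwm):
        """No window can out-score the consensus (rel_score is capped at 1)."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        hits = v.scan(seq, klf4_pwm, rel_threshold=0.1)
        assert all(h.rel_score <= 1.0 for h in hits)
        consensus_hits = v.scan(v.KLF4_CONSENSUS, klf4_pwm, rel_threshold=1.0)
        assert consensus_hits[0].score == pytest.approx(klf4_pwm.max_score)

    def test_n_bases_never_score(self, klf4_pwm):
        seq = "AGGGGTNGAGTC"
        assert v.scan(seq, klf4_pwm, rel_threshold=0.5) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_symmetry_oracle(self, klf4_pwm, seed):
        """scan(revcomp(S)) mirrors scan(S): strands swap, positions reflect."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        seq = seq[:100] + v.KLF4_CONSENSUS + seq[100:]  # guarantee >=1 hit
        w = klf4_pwm.width
        fwd = v.scan(seq, klf4_pwm, rel_threshold=0.75)
        rev = v.scan(revcomp(seq), klf4_pwm, rel_threshold=0.75)
        mirror = {
            (len(seq) - w - h.start, "+-"[h.strand == "+"], round(h.score, 6))
            for h in fwd
        }
        observed = {(h.start, h.strand, round(h.score, 6)) for h in rev}
        assert mirror == observed

    def test_invalid_threshold(self, klf4_pwm):
        with pytest.raises(ValueError):
            v.scan("ACGTACGTACGT", klf4_pwm, rel_threshold=0.0)


class TestShuffleEnrichment:
    def test_planted_regions_maximally_significant(self, klf4_pwm):
        rng = np.random.default_rng(1)
        regions = []
        for _ in range(8):
            bg = "".join(rng.choice(list("ACGT"), size=120))
            regions.append(bg[:50] + v.KLF4_CONSENSUS + bg[50:])
        result = v.shuffle_enrichment(regions, klf4_pwm, n_shuffles=49, seed=2)
        assert result.observed_hits >= 8
        assert result.p_value == pytest.approx(1 / 50)

    def test_shuffle_preserves_composition(self):
        rng = np.random.default_rng(0)
        seq = "AAACCCGGGTTTAAACGT"
        shuffled = _mononucleotide_shuffle(seq, rng)
        assert sorted(shuffled) == sorted(seq)
        assert shuffled != seq

    def test_null_regions_not_significant(self, klf4_pwm):
        """Without planting, p-values stay away from the minimum."""
        rng = np.random.default_rng(4)
        pvals = []
        for trial in range(20):
            regions = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(4)]
            res = v.shuffle_enrichment(regions, klf4_pwm, n_shuffles=19, seed=trial)
            pvals.append(res.p_value)
        assert np.mean(pvals) > 0.3  # roughly uniform null, not piled at 1/20

    def test_empty_regions_and_zero_shuffles_rejected(self, klf4_pwm):
        with pytest.raises(ValueError):
            v.shuffle_enrichment([], klf4_pwm, n_shuffles=10, seed=0)
        with pytest.raises(ValueError):
            v.shuffle_enrichment(["ACGTACGTACGTACGT"], klf4_pwm, n_shuffles=0, seed=0)


class TestSiteMatrix:
    def test_constant_coverage_fills_every_cell(self):
        coverage = {"c1": np.full(50_000, 3.5)}
        sites = [("c1", 20_000), ("c1", 30_000)]
        matrix = v.site_matrix(sites, coverage, window_bp=10_000, bin_size_bp=1_000)
        assert matrix.values.shape == (2, 20)
        assert np.allclose(matrix.values, 3.5)

    def test_delta_signal_lands_in_central_column(self):
        coverage = {"c1": np.zeros(50_000)}
        anchors = [("c1", 20_000), ("c1", 35_000)]
        for chrom, pos in anchors:
            coverage[chrom][pos] = 1.0
        matrix = v.site_matrix(anchors, coverage, window_bp=10_000, bin_size_bp=1_000)
        nonzero_cols = {int(c) for c in np.nonzero(matrix.values)[1]}
        assert nonzero_cols == {10}  # bin starting at the anchor itself

    def test_100kb_bin_configuration(self):
        coverage = {"c1": np.ones(3_000_000)}
        matrix = v.site_matrix(
            [("c1", 1_500_000)], coverage, window_bp=500_000, bin_size_bp=100_000
        )
        assert matrix.n_bins == 10

    def test_out_of_chrom_bins_are_zero(self):
        coverage = {"c1": np.ones(5_000)}
        matrix = v.site_matrix([("c1", 500)], coverage, window_bp=2_000, bin_size_bp=500)
        # window [-1500, 2500): first 3 bins fall fully before the chromosome
        assert np.allclose(matrix.values[0, :3], 0.0)
        assert np.allclose(matrix.values[0, 4:], 1.0)

    def test_rows_sorted_by_descending_total(self):
        coverage = {"c1": np.zeros(30_000)}
        coverage["c1"][20_000:21_000] = 5.0
        sites = [("c1", 5_000), ("c1", 20_500)]
        matrix = v.site_matrix(sites, coverage, window_bp=2_000, bin_size_bp=500)
        assert matrix.row_order == [1, 0]
        assert matrix.values[0].sum() > matrix.values[1].sum()

    def test_row_mean_invariant_to_bin_refinement(self):
        """Piecewise-constant coverage: refining bins preserves row means."""
        rng = np.random.default_rng(5)
        block = np.repeat(rng.uniform(0, 10, size=40), 1_000)  # constant per kb
        coverage = {"c1": block}
        sites = [("c1", 20_000)]
        coarse = v.site_matrix(sites, coverage, window_bp=10_000, bin_size_bp=1_000)
        fine = v.site_matrix(sites, coverage, window_bp=10_000, bin_size_bp=250)
        assert coarse.values.mean() == pytest.approx(fine.values.mean())

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            v.site_matrix([("c1", 0)], {"c1": np.zeros(10)}, 1000, 300)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            v.site_matrix([], {"c1": np.zeros(10)}, 1000, 100)


def test_coverage_from_bedgraph_round_trip():
    records = [("c1", 0, 5, 2.0), ("c1", 5, 10, 1.0)]
    cov = coverage_from_bedgraph(records, {"c1": 12})
    assert np.array_equal(cov["c1"], [2] * 5 + [1] * 5 + [0] * 2)


def test_jaspar_pfm_reader(tmp_path):
    path = tmp_path / "klf4.jaspar"
    path.write_text(
        ">MA0039.x KLF4\n"
        "A [ 10  0  1  0 ]\n"
        "C [  0  1  0  8 ]\n"
        "G [  0  9  0  0 ]\n"
        "T [  0  0  9  2 ]\n"
    )
    pwm = v.read_jaspar_pfm(path)
    assert pwm.width == 4
    assert pwm.consensus == "AGTC"
    assert "MA0039.x" in pwm.name
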