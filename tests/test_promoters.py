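"""Promoter windows, binning, normalization, CpG counting and the split."""

import numpy as np
import pytest
from scipy import optimize, stats

from cpgfuse.promoters import (POOR, RICH, PromoterRegion, aggregate_response,
                               bin_signal, count_cpg, define_promoter_windows,
                               fit_bimodal_split, normalize_log_unit)


def region(strand="+", tss=10000, up=500, down=500, k=10, gene="g1"):
    recs = [dict(gene_id=gene, chrom="chr1", tss=tss, strand=strand)]
    return define_promoter_windows(recs, up, down, k)[0]


class TestWindows:
    def test_plus_strand_window_and_bins(self):
        r = region("+")
        assert (r.start, r.end) == (9500, 10500)
        assert list(r.bin_edges[:2]) == [9500, 9600]

    def test_minus_strand_same_interval(self):
        r = region("-")
        assert (r.start, r.end) == (9500, 10500)
        # bin 0 is the genomically rightmost 100 bp for a minus-strand gene
        cov = np.zeros(1000)
        cov[900:] = 1.0
        np.testing.assert_array_equal(bin_signal(cov, r)[0], 1.0)

    def test_clip_below_zero_flagged(self):
        r = region("+", tss=300)
        assert r.excluded and r.start == 0

    def test_duplicate_gene_rejected(self):
        recs = [dict(gene_id="g", chrom="chr1", tss=1000, strand="+")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            define_promoter_windows(recs)

    def test_missing_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            define_promoter_windows(
                [dict(gene_id="g", chrom="chr1", tss=1000, strand=None)])


class TestBinning:
    def test_constant_coverage(self):
        r = region("+")
        np.testing.assert_allclose(bin_signal(np.full(1000, 2.0), r), 2.0)

    def test_first_bin_plus(self):
        r = region("+")
        cov = np.zeros(1000)
        cov[:100] = 1.0
        np.testing.assert_array_equal(bin_signal(cov, r),
                                      [1] + [0] * 9)

    def test_minus_strand_is_reversal(self):
        """Binning a minus-strand region equals binning the reversed
        coverage of a plus-strand region at the same locus."""
        rng = np.random.default_rng(0)
        cov = rng.uniform(size=1000)
        rp, rm = region("+"), region("-")
        np.testing.assert_allclose(bin_signal(cov, rm),
                                   bin_signal(cov[::-1], rp))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bin_signal(np.ones(999), region("+"))

    def test_tiling_conservation(self):
        rng = np.random.default_rng(1)
        cov = rng.exponential(size=1000)
        r = region("+")
        assert aggregate_response(cov, r) == pytest.approx(
            bin_signal(cov, r).mean(), abs=1e-12)

    def test_aggregate_examples(self):
        assert aggregate_response(np.full(10, 3.5)) == 3.5
        assert aggregate_response(np.r_[np.zeros(5), np.ones(5)]) == 0.5


class TestNormalization:
    def test_log_symmetry_example(self):
        np.testing.assert_allclose(
            normalize_log_unit(np.array([0.0, 9.0, 99.0])), [0, 0.5, 1.0],
            atol=1e-12)

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(normalize_log_unit(np.full(5, 7.0)),
                                      np.zeros(5))

    def test_bounds_attained(self):
        rng = np.random.default_rng(2)
        out = normalize_log_unit(rng.exponential(size=100))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_log_unit(np.array([-1.0, 2.0]))

    def test_round_trip_inverse(self):
        """Applying the exp/shift inverse then re-normalizing is identity."""
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(size=50))
        x[0], x[-1] = 0.0, 1.0
        lo, hi = 0.3, 4.2
        values = np.exp(x * (hi - lo) + lo) - 1.0
        np.testing.assert_allclose(normalize_log_unit(values), x, atol=1e-9)


class TestCpGCounting:
    @pytest.mark.parametrize("seq,width,total,profile", [
        ("CGCGCG", 6, 3, [3]),
        ("ATATAT", 6, 0, [0]),
        ("ACGTACGT", 4, 2, [1, 1]),
    ])
    def test_examples(self, seq, width, total, profile):
        t, p = count_cpg(seq, bin_width=width)
        assert t == total
        np.testing.assert_array_equal(p, profile)

    def test_straddling_cg_assigned_to_c_bin(self):
        t, p = count_cpg("AACG", bin_width=3)  # C at index 2, G at 3
        assert t == 1
        np.testing.assert_array_equal(p, [1, 0])

    def test_length_check(self):
        with pytest.raises(ValueError):
            count_cpg("ACGT", expected_length=10)


class TestBimodalSplit:
    def test_symmetric_threshold_near_midpoint(self):
        rng = np.random.default_rng(5)
        counts = np.r_[rng.normal(20, 3, 5000), rng.normal(60, 3, 5000)]
        counts = np.maximum(0, np.rint(counts))
        part = fit_bimodal_split(counts, seed=0)
        assert part.threshold == pytest.approx(40.0, abs=1.0)
        g1, g2 = part.gauss1, part.gauss2
        assert g1[1] < part.threshold < g2[1]

    def test_em_recovers_means_within_3se(self):
        rng = np.random.default_rng(6)
        n = 10000
        counts = np.r_[rng.normal(15, 2, int(0.3 * n)),
                       rng.normal(50, 6, int(0.7 * n))]
        part = fit_bimodal_split(counts, seed=0)
        assert abs(part.gauss1[1] - 15) < 3 * 2 / np.sqrt(0.3 * n) + 0.1
        assert abs(part.gauss2[1] - 50) < 3 * 6 / np.sqrt(0.7 * n) + 0.1

    def test_labels_follow_threshold_and_partition(self):
        rng = np.random.default_rng(7)
        counts = np.r_[rng.normal(20, 3, 500), rng.normal(60, 3, 500)]
        part = fit_bimodal_split(counts, seed=0)
        np.testing.assert_array_equal(
            part.labels, np.where(part.counts < part.threshold, POOR, RICH))
        assert part.n_poor + part.n_rich == 1000

    def test_asymmetric_threshold_matches_true_density_root(self):
        rng = np.random.default_rng(8)
        n = 20000
        counts = np.r_[rng.normal(15, 2, int(0.3 * n)),
                       rng.normal(50, 6, int(0.7 * n))]
        part = fit_bimodal_split(counts, seed=0)

        def true_diff(x):
            return (0.3 * stats.norm.pdf(x, 15, 2)
                    - 0.7 * stats.norm.pdf(x, 50, 6))

        true_root = optimize.brentq(true_diff, 15, 50)
        assert part.threshold == pytest.approx(true_root, abs=0.5)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_bimodal_split(np.full(100, 42.0))
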