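"""Generator tests: mixture moments, determinism, identifiability."""

import dataclasses

import numpy as np
import pytest

from cpgfuse.promoters import normalize_log_unit
from cpgfuse.synthetic import (POOR, RICH, MixtureComponent, SyntheticConfig,
                               block_coefficients, generate_cpg_counts,
                               generate_dataset, generate_hm_response,
                               generate_tf_signals, mixture_threshold,
                               noise_sd_for_r2)


def _cfg(**kw):
    base = dict(n_genes=100, n_tfs=3, n_bins=4,
                planted={POOR: [{}], RICH: [{}]}, noise_sd=0.0, seed=1)
    base.update(kw)
    return SyntheticConfig(**base)


class TestCpGCounts:
    def test_degenerate_mixture_all_zero(self):
        cfg = _cfg(cpg_mixture=(MixtureComponent(0.4, 0.0, 0.0),
                                MixtureComponent(0.6, 0.0, 0.0)))
        counts, labels = generate_cpg_counts(cfg)
        assert np.all(counts == 0)
        assert set(labels) == {POOR, RICH}  # labels still mixed per weights

    def test_mixture_mean_within_3se(self):
        cfg = _cfg(n_genes=10000,
                   cpg_mixture=(MixtureComponent(0.5, 20.0, 3.0),
                                MixtureComponent(0.5, 60.0, 3.0)))
        counts, _ = generate_cpg_counts(cfg)
        # analytic mixture mean 40; var = E[var] + var of means
        var = 0.5 * 9 + 0.5 * 9 + 0.5 * 400 + 0.5 * 400 - 0  # 9 + 400
        se = np.sqrt((9 + 400) / 10000)
        assert abs(counts.mean() - 40.0) < 3 * se + 0.5  # +0.5 for rounding

    def test_seed_determinism(self):
        cfg = _cfg(n_genes=500)
        c1, l1 = generate_cpg_counts(cfg)
        c2, l2 = generate_cpg_counts(cfg)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(l1, l2)

    def test_negative_sd_rejected(self):
        cfg = _cfg(cpg_mixture=(MixtureComponent(0.5, 10, -1.0),
                                MixtureComponent(0.5, 20, 1.0)))
        with pytest.raises(ValueError):
            generate_cpg_counts(cfg)


class TestTfSignals:
    def test_zero_scale_constant(self):
        X = generate_tf_signals(_cfg(background=(1.5, 0.0)))
        np.testing.assert_allclose(X, np.exp(1.5))

    def test_strictly_positive_and_deterministic(self):
        cfg = _cfg(background=(0.0, 2.0))
        X1 = generate_tf_signals(cfg)
        X2 = generate_tf_signals(cfg)
        assert X1.min() > 0
        np.testing.assert_array_equal(X1, X2)


class TestHmResponse:
    def test_empty_planted_no_noise_constant(self):
        cfg = _cfg()
        X = generate_tf_signals(cfg)
        _, labels = generate_cpg_counts(cfg)
        y = generate_hm_response(X, labels, cfg)
        np.testing.assert_allclose(y, 0.0)

    def test_single_tf_unit_coefs_perfect_correlation(self):
        k = 4
        planted = {cls: [{0: np.ones(k)}] for cls in (POOR, RICH)}
        cfg = _cfg(planted=planted, n_genes=200)
        X = generate_tf_signals(cfg)
        _, labels = generate_cpg_counts(cfg)
        y = generate_hm_response(X, labels, cfg)[:, 0]
        for cls in (POOR, RICH):
            rows = labels == cls
            Xn = np.column_stack([normalize_log_unit(X[rows, j])
                                  for j in range(k)])  # TF0's bins
            mean_sig = Xn.mean(axis=1)
            r = np.corrcoef(y[rows], mean_sig)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_ols_recovers_planted(self):
        k = 4
        coefs = np.array([1.0, 1.0, -2.0, 0.5])
        planted = {cls: [{1: coefs}] for cls in (POOR, RICH)}
        cfg = _cfg(planted=planted, n_genes=300)
        X = generate_tf_signals(cfg)
        _, labels = generate_cpg_counts(cfg)
        y = generate_hm_response(X, labels, cfg)[:, 0]
        rows = labels == RICH
        Xn = np.column_stack([normalize_log_unit(X[rows, j])
                              for j in range(k, 2 * k)])
        A = np.column_stack([np.ones(rows.sum()), Xn])
        sol, res, *_ = np.linalg.lstsq(A, y[rows], rcond=None)
        np.testing.assert_allclose(sol[1:], coefs, atol=1e-6)
        rss = float(np.sum((y[rows] - A @ sol) ** 2))
        assert rss < 1e-12

    def test_out_of_range_tf_rejected(self):
        planted = {cls: [{5: np.ones(4)}] for cls in (POOR, RICH)}
        cfg = _cfg(planted=planted)
        with pytest.raises(ValueError):
            generate_hm_response(generate_tf_signals(_cfg()),
                                 np.array([POOR] * 100), cfg)


class TestDataset:
    def test_dimensions_and_determinism(self, small_planted_config):
        ds1 = generate_dataset(small_planted_config)
        ds2 = generate_dataset(small_planted_config)
        cfg = small_planted_config
        assert ds1.tf_raw.shape == (cfg.n_genes, cfg.n_tfs * cfg.n_bins)
        assert ds1.hm_raw.shape == (cfg.n_genes, cfg.n_hms)
        np.testing.assert_array_equal(ds1.tf_raw, ds2.tf_raw)
        np.testing.assert_array_equal(ds1.hm_raw, ds2.hm_raw)
        np.testing.assert_array_equal(ds1.cpg_counts, ds2.cpg_counts)

    def test_different_seeds_differ(self, small_planted_config):
        ds1 = generate_dataset(small_planted_config)
        ds2 = generate_dataset(
            dataclasses.replace(small_planted_config,
                                seed=small_planted_config.seed + 1))
        assert not np.array_equal(ds1.tf_raw, ds2.tf_raw)

    def test_true_threshold_is_density_root(self, small_planted_config):
        ds = generate_dataset(small_planted_config)
        from scipy import stats
        c1, c2 = small_planted_config.cpg_mixture
        t = ds.truth.threshold
        d1 = c1.weight * stats.norm.pdf(t, c1.mean, c1.sd)
        d2 = c2.weight * stats.norm.pdf(t, c2.mean, c2.sd)
        assert d1 == pytest.approx(d2, rel=1e-6)
        assert c1.mean < t < c2.mean


class TestNoiseCalibration:
    def test_noise_sd_hits_target_r2(self):
        k = 6
        planted = {cls: [{0: block_coefficients(k, 0, k, 2.0)}]
                   for cls in (POOR, RICH)}
        cfg = _cfg(n_genes=2000, n_tfs=2, n_bins=k, planted=planted)
        sd = noise_sd_for_r2(cfg, 0.8)
        noisy = dataclasses.replace(cfg, noise_sd=sd)
        X = generate_tf_signals(noisy)
        _, labels = generate_cpg_counts(noisy)
        y = generate_hm_response(X, labels, noisy)[:, 0]
        rows = labels == RICH
        Xn = np.column_stack([normalize_log_unit(X[rows, j])
                              for j in range(k)])
        A = np.column_stack([np.ones(rows.sum()), Xn])
        sol = np.linalg.lstsq(A, y[rows], rcond=None)[0]
        resid = y[rows] - A @ sol
        r2 = 1 - resid.var() / y[rows].var()
        assert r2 == pytest.approx(0.8, abs=0.06)


def test_symmetric_mixture_threshold_is_midpoint():
    t = mixture_threshold(MixtureComponent(0.5, 20, 3),
                          MixtureComponent(0.5, 60, 3))
    assert t == pytest.approx(40.0, abs=1e-9)
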