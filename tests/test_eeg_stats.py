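"""Cluster randomization, jackknife peak estimation, topography similarity."""

import math

import numpy as np
import pytest

from neuropd.eeg_stats import (attach_frequencies, cluster_randomization_test,
                               compare_peaks, jackknife_peak,
                               jackknife_pseudo_values,
                               topography_similarity_test)

GRID = 2.0 ** (1.0 + np.arange(41) / 8.0)


def _null_spectra(rng, n_sub=12, n_freq=41, sd=1.0):
    """Null spectra with frequency-correlated subject noise.

    The wavelet estimator smooths over half an octave, so neighbouring
    grid frequencies of real pipeline spectra are strongly correlated;
    the simulated estimation noise is smoothed accordingly (~2 grid bins).
    """
    from scipy.ndimage import gaussian_filter1d
    base = 10.0 / np.arange(1, n_freq + 1)
    noise = gaussian_filter1d(rng.normal(0, sd * 0.05, (n_sub, n_freq)),
                              2.0, axis=1, mode="nearest")
    return base + noise


class TestClusterTest:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(0)
        a = _null_spectra(rng)
        res = cluster_randomization_test(a, a.copy(), n_perm=200, seed=1)
        assert res.clusters == []

    def test_unmatched_subjects_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            cluster_randomization_test(_null_spectra(rng),
                                       _null_spectra(rng)[:-1], n_perm=100)
        with pytest.raises(ValueError):
            cluster_randomization_test(_null_spectra(rng, 4),
                                       _null_spectra(rng, 4), n_perm=100)

    def test_detects_broad_injected_effect(self):
        """A +20% band effect over 6-9 Hz yields a positive significant
        cluster overlapping that band in at least 90% of repetitions."""
        band = (GRID >= 6.0) & (GRID <= 9.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            b = _null_spectra(rng)
            a = b.copy()
            a[:, band] *= 1.20
            a += rng.normal(0, 0.05, a.shape)
            res = cluster_randomization_test(a, b, n_perm=1000, seed=seed)
            attach_frequencies(res, GRID)
            hits += any(c.sign > 0 and c.p_value < 0.05
                        and c.start_hz <= 9.0 and c.end_hz >= 6.0
                        for c in res.clusters)
        assert hits >= 90

    def test_type_one_error_rate_controlled(self):
        """Under the null the familywise any-cluster rate at alpha = 0.05
        stays near nominal (500 simulated datasets)."""
        false_pos = 0
        for seed in range(500):
            rng = np.random.default_rng(10_000 + seed)
            a = _null_spectra(rng)
            b = _null_spectra(rng)
            res = cluster_randomization_test(a, b, n_perm=1000, seed=seed)
            false_pos += bool(res.significant(0.05))
        assert 0.02 <= false_pos / 500 <= 0.09

    def test_invariant_to_subject_level_offsets(self):
        """Adding a per-subject constant to both conditions leaves paired
        differences, hence t-values and p-values, unchanged."""
        rng = np.random.default_rng(3)
        a, b = _null_spectra(rng), _null_spectra(rng)
        shift = rng.normal(0, 5.0, (12, 1))
        r1 = cluster_randomization_test(a, b, n_perm=500, seed=7)
        r2 = cluster_randomization_test(a + shift, b + shift, n_perm=500, seed=7)
        np.testing.assert_allclose(r1.t_values, r2.t_values, rtol=1e-10)
        assert [c.p_value for c in r1.clusters] == \
            [c.p_value for c in r2.clusters]

    def test_p_values_stable_across_seeds_at_large_n_perm(self):
        rng = np.random.default_rng(4)
        b = _null_spectra(rng)
        a = b.copy()
        a[:, 10:16] *= 1.08
        a += rng.normal(0, 0.04, a.shape)
        ps = []
        for seed in range(5):
            res = cluster_randomization_test(a, b, n_perm=10000, seed=seed)
            assert res.clusters
            ps.append(max(c.p_value for c in res.clusters))
        assert np.std(ps) < 0.01

    def test_exhaustive_enumeration_for_small_samples(self):
        rng = np.random.default_rng(5)
        a = _null_spectra(rng, n_sub=8)
        b = a + rng.normal(0.02, 0.03, a.shape)
        r1 = cluster_randomization_test(a, b, n_perm=1000, seed=0)
        r2 = cluster_randomization_test(a, b, n_perm=1000, seed=99)
        assert r1.exhaustive and r1.n_perm == 256
        assert [c.p_value for c in r1.clusters] == \
            [c.p_value for c in r2.clusters]  # seed-independent

    def test_cluster_mass_statistic_option(self):
        rng = np.random.default_rng(6)
        b = _null_spectra(rng)
        a = b.copy()
        a[:, 12:18] *= 1.15
        a += rng.normal(0, 0.04, a.shape)
        res = cluster_randomization_test(a, b, n_perm=500, seed=0,
                                         statistic="mass")
        assert res.clusters and res.significant(0.05)


class TestJackknifePeak:
    def test_identical_subjects_zero_sem(self):
        spec = np.exp(-(np.log2(GRID) - math.log2(7.3)) ** 2 / 0.08)
        x = np.tile(spec, (6, 1))
        est = jackknife_peak(x, GRID, band=(4.0, 13.0))
        assert est.sem_hz == pytest.approx(0.0, abs=1e-12)
        assert est.mean_hz == pytest.approx(7.3, abs=0.15)

    def test_pseudo_value_identity_for_linear_statistic(self):
        """For a statistic linear in subjects (mean power at one frequency)
        the pseudo-value mean equals the full-sample statistic exactly."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (9, 41))
        pseudo, full = jackknife_pseudo_values(x, lambda s: s.mean(axis=0)[7])
        assert pseudo.mean() == pytest.approx(full, rel=1e-12)

    def test_flat_spectrum_flagged(self):
        est = jackknife_peak(np.ones((5, 41)), GRID, band=(4.0, 13.0))
        assert est.flat

    def test_negative_effect_peak(self):
        spec = -np.exp(-(np.log2(GRID) - math.log2(34.9)) ** 2 / 0.08)
        x = np.tile(spec, (6, 1)) + np.random.default_rng(1).normal(
            0, 0.01, (6, 41))
        est = jackknife_peak(x, GRID, band=(20.0, 60.0), mode="min")
        assert est.mean_hz == pytest.approx(34.9, rel=0.05)

    def test_distinct_peaks_distinguished(self):
        """Two drugs with effect peaks at 18.4 vs 34.9 Hz differ at p < 0.05
        in at least 90% of repetitions with 12 subjects each."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)

            def drug_spectra(center):
                jitter = rng.normal(0, 0.1, 12)  # per-subject peak offsets
                return np.stack([
                    np.exp(-(np.log2(GRID) - math.log2(center) - j) ** 2 / 0.08)
                    for j in jitter]) + rng.normal(0, 0.05, (12, 41))

            pa = jackknife_peak(drug_spectra(18.4), GRID, band=(10.0, 60.0))
            pb = jackknife_peak(drug_spectra(34.9), GRID, band=(10.0, 60.0))
            wins += compare_peaks(pa, pb) < 0.05
        assert wins >= 90


class TestTopographyTest:
    def test_shared_topography_is_null(self):
        """When both drugs express the same spatial pattern (plus noise)
        the within-minus-between statistic is near zero."""
        rng = np.random.default_rng(2)
        common = rng.normal(0, 1, 19)
        a = common + rng.normal(0, 0.4, (12, 19))
        b = common + rng.normal(0, 0.4, (12, 19))
        res = topography_similarity_test(a, b, n_perm=2000, seed=0)
        assert abs(res.statistic) < 0.1
        assert res.p_value > 0.05

    def test_orthogonal_patterns_detected(self):
        """Orthogonal group patterns with subject noise are separated at
        p < 0.01 in at least 90% of repetitions."""
        pat_a = np.zeros(19); pat_a[:10] = 1.0
        pat_b = np.zeros(19); pat_b[10:] = 1.0
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = pat_a + rng.normal(0, 0.5, (12, 19))
            b = pat_b + rng.normal(0, 0.5, (12, 19))
            res = topography_similarity_test(a, b, n_perm=1000, seed=seed)
            hits += res.p_value < 0.01
        assert hits >= 90

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (8, 19))
        b = rng.normal(0, 1, (8, 19))
        r1 = topography_similarity_test(a, b, n_perm=500, seed=0)
        r2 = topography_similarity_test(a[::-1], b[::-1], n_perm=500, seed=0)
        assert r1.r_within == pytest.approx(r2.r_within)
        assert r1.r_between == pytest.approx(r2.r_between)

    def test_type_one_error_rate(self):
        """With exchangeable labels the rejection rate at 0.05 stays within
        [0.03, 0.08] over 500 simulated datasets."""
        rejections = 0
        for seed in range(500):
            rng = np.random.default_rng(20_000 + seed)
            pool = rng.normal(0, 1, (24, 19))
            res = topography_similarity_test(pool[:12], pool[12:],
                                             n_perm=500, seed=seed)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / 500 <= 0.08

    def test_zero_variance_topography_excluded(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (5, 19))
        a[2] = 3.14  # flat topography: correlation undefined
        b = rng.normal(0, 1, (5, 19))
        res = topography_similarity_test(a, b, n_perm=200, seed=0)
        assert res.excluded_subjects == [2]

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            topography_similarity_test(rng.normal(0, 1, (2, 19)),
                                       rng.normal(0, 1, (5, 19)))
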