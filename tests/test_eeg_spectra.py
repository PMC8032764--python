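"""Preprocessing, wavelet spectra, alpha alignment and power change."""

import math

import numpy as np
import pytest

from neuropd.eeg_spectra import (AlphaPeak, EEGRecording, SpectralEstimate,
                                 align_to_mean_alpha, band_topography,
                                 detect_alpha_peak, fft_spectrum,
                                 power_change, preprocess, relative_power,
                                 wavelet_power)

CH2 = ("O1", "O2")


def _rec(data, fs=256.0, channels=CH2, **kw):
    return EEGRecording(data=data, fs=fs, channels=channels, **kw)


def _sine(freq, fs=256.0, dur=60.0, amp=1e-5, n_ch=2):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.sin(2 * math.pi * freq * t) * np.ones((n_ch, 1))


class TestPreprocess:
    def test_line_noise_attenuated_20db(self):
        rec = preprocess(_rec(_sine(50.0)))
        good = ~rec.bad_mask
        out_var = rec.data[:, good].var()
        in_var = _sine(50.0)[:, good].var()
        assert out_var < in_var * 0.01  # >= 20 dB

    def test_dc_removed_by_highpass(self):
        rec = preprocess(_rec(np.full((2, 256 * 30), 5e-5)))
        assert np.abs(rec.data[:, ~rec.bad_mask]).max() < 1e-9

    def test_average_reference_identity(self):
        rng = np.random.default_rng(0)
        rec = preprocess(_rec(rng.normal(0, 1e-5, (4, 256 * 30)),
                              channels=("O1", "O2", "C3", "C4")))
        assert np.abs(rec.data.mean(axis=0)).max() < 1e-10

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            preprocess(_rec(np.zeros((2, 256))))

    def test_artifact_segment_marked_bad(self):
        x = np.random.default_rng(1).normal(0, 5e-6, (2, 256 * 30))
        x[0, 256 * 10:256 * 10 + 50] += 500e-6  # big transient at t = 10 s
        rec = preprocess(_rec(x))
        assert rec.bad_mask[256 * 10 + 25]
        assert not rec.bad_mask[256 * 20]

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            preprocess(_rec(np.zeros((2, 6400)), fs=100.0))


class TestWaveletPower:
    def test_sinusoid_peaks_at_nearest_grid_frequency(self, grid):
        spec = wavelet_power(_rec(_sine(9.3)), grid)
        peak = grid.freqs_hz[np.nanargmax(spec.channel_mean())]
        nearest = grid.freqs_hz[np.abs(grid.freqs_hz - 9.3).argmin()]
        assert peak == nearest

    def test_amplitude_doubling_quadruples_power(self, grid):
        x = _sine(12.0)
        p1 = wavelet_power(_rec(x), grid).power
        p2 = wavelet_power(_rec(2 * x), grid).power
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-6)

    def test_time_shift_invariance_for_stationary_signal(self, grid):
        rng = np.random.default_rng(3)
        long = rng.normal(0, 1e-5, (2, 256 * 130))
        a = wavelet_power(_rec(long[:, :256 * 120]), grid).channel_mean()
        b = wavelet_power(_rec(long[:, 256:256 * 120 + 256]), grid).channel_mean()
        np.testing.assert_allclose(a, b, rtol=0.05)

    def test_white_noise_density_calibration(self, grid):
        """For white noise of variance s^2 the per-log2(Hz) density is
        s^2/(fs/2) * f * ln 2 (averaged over realizations; the lowest
        octave has few independent estimation windows per recording)."""
        rng = np.random.default_rng(7)
        est = np.mean([
            wavelet_power(_rec(rng.normal(0, 1e-5, (2, 256 * 120))),
                          grid).channel_mean()
            for _ in range(5)], axis=0)
        expected = 1e-10 / 128.0 * grid.freqs_hz * math.log(2)
        assert np.all(np.abs(est / expected - 1) < 0.1)

    def test_too_short_recording_raises(self, grid):
        with pytest.raises(ValueError, match="too short"):
            wavelet_power(_rec(np.zeros((2, 256))), grid)

    def test_bad_segments_excluded(self, grid):
        """A huge artifact inside a masked segment must not leak into the
        spectrum."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1e-5, (2, 256 * 60))
        clean = wavelet_power(_rec(x.copy()), grid).channel_mean()
        x2 = x.copy()
        x2[:, 256 * 30:256 * 31] += 1.0  # enormous transient
        bad = np.zeros(x.shape[1], bool)
        bad[256 * 28:256 * 33] = True
        dirty = wavelet_power(_rec(x2, bad_mask=bad), grid).channel_mean()
        np.testing.assert_allclose(dirty, clean, rtol=0.25)
        assert dirty.max() < 10 * clean.max()


class TestFrequencyGrid:
    def test_grid_definition(self, grid):
        assert grid.freqs_hz.size == 41
        assert grid.freqs_hz[0] == pytest.approx(2.0)
        assert grid.freqs_hz[-1] == pytest.approx(64.0)
        assert grid.step_octaves == pytest.approx(0.125)
        assert grid.q == pytest.approx(5.83)


def _bump_spec(center_hz, grid, width_oct=0.2, bg=1.0, height=5.0, n_ch=2):
    lf = grid.log2_freqs
    p = bg / grid.freqs_hz + height * np.exp(
        -(lf - math.log2(center_hz)) ** 2 / (2 * width_oct ** 2))
    return SpectralEstimate(power=np.tile(p, (n_ch, 1)), grid=grid,
                            channels=CH2[:n_ch], subject="S")


class TestAlphaPeak:
    def test_bump_maps_to_nearest_grid_frequency(self, grid):
        peak = detect_alpha_peak(_bump_spec(9.85, grid))
        nearest = grid.freqs_hz[np.abs(grid.freqs_hz - 9.85).argmin()]
        assert peak.freq_hz == nearest
        assert not peak.at_boundary

    def test_on_grid_bump_is_exact(self, grid):
        f0 = grid.freqs_hz[18]  # 9.51 Hz, inside the 7-12 Hz search range
        peak = detect_alpha_peak(_bump_spec(f0, grid))
        assert peak.freq_hz == f0

    def test_monotone_spectrum_flags_boundary(self, grid):
        spec = SpectralEstimate(power=np.tile(1.0 / grid.freqs_hz, (2, 1)),
                                grid=grid, channels=CH2)
        peak = detect_alpha_peak(spec)
        assert peak.at_boundary
        assert peak.freq_hz == grid.freqs_hz[grid.freqs_hz >= 7.0][0]

    def test_fft_variant_finds_sinusoid(self):
        freqs, power = fft_spectrum(_rec(_sine(9.85, dur=30.0)))
        sel = (freqs >= 7) & (freqs <= 12)
        assert freqs[sel][np.argmax(power[sel])] == pytest.approx(9.85, abs=0.1)


class TestAlignment:
    def test_identity_when_peak_equals_target(self, grid):
        spec = _bump_spec(9.3, grid)
        out = align_to_mean_alpha(spec, AlphaPeak("S", 9.3), target_hz=9.3)
        np.testing.assert_allclose(out.power, spec.power)

    def test_one_grid_step_shift_is_index_shift(self, grid):
        spec = _bump_spec(8.0, grid)
        f_lo = grid.freqs_hz[10]
        out = align_to_mean_alpha(spec, AlphaPeak("S", f_lo),
                                  target_hz=grid.freqs_hz[11])
        np.testing.assert_allclose(out.power[:, 1:], spec.power[:, :-1],
                                   rtol=1e-12)
        assert np.isnan(out.power[:, 0]).all()

    def test_detect_after_alignment_hits_target(self, grid):
        """Re-detected peaks land on the target to grid resolution (the
        grid is 1/8-octave; interpolation of a non-integer shift can move
        an argmax by up to one step)."""
        for f0 in (8.0, 9.0, 11.0):
            spec = _bump_spec(f0, grid)
            peak = detect_alpha_peak(spec)
            aligned = align_to_mean_alpha(spec, peak, target_hz=9.3)
            new_peak = detect_alpha_peak(aligned)
            assert abs(math.log2(new_peak.freq_hz / 9.3)) <= 0.125 + 1e-9

    def test_shift_recorded_in_octaves(self, grid):
        out = align_to_mean_alpha(_bump_spec(8.0, grid), AlphaPeak("S", 8.0),
                                  target_hz=9.3)
        assert out.shift_octaves == pytest.approx(math.log2(9.3 / 8.0))


class TestRelativePower:
    def test_unit_sum_per_channel(self, grid):
        out = relative_power(_bump_spec(9.3, grid))
        np.testing.assert_allclose(np.nansum(out.power, axis=1), 1.0)
        assert out.kind == "relative"

    def test_flat_spectrum_uniform(self, grid):
        spec = SpectralEstimate(power=np.full((2, 41), 3.3), grid=grid,
                                channels=CH2)
        np.testing.assert_allclose(relative_power(spec).power, 1.0 / 41)

    def test_scale_invariance(self, grid):
        spec = _bump_spec(9.3, grid)
        a = relative_power(spec).power
        spec.power = spec.power * 123.4
        b = relative_power(spec).power
        np.testing.assert_allclose(a, b)

    def test_zero_total_rejected(self, grid):
        spec = SpectralEstimate(power=np.zeros((2, 41)), grid=grid,
                                channels=CH2)
        with pytest.raises(ValueError):
            relative_power(spec)


class TestPowerChange:
    def test_identical_conditions_give_zero(self, grid):
        spec = _bump_spec(9.3, grid)
        subjects, ch, mean = power_change({"S": [spec]}, {"S": [spec]})
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(ch, 0.0)

    def test_subject_mismatch_rejected(self, grid):
        spec = _bump_spec(9.3, grid)
        with pytest.raises(ValueError):
            power_change({"A": [spec]}, {"B": [spec]})

    def test_channel_mean_consistent_with_channel_resolved(self, grid):
        rng = np.random.default_rng(0)
        drug, base = {}, {}
        for s in ("S1", "S2"):
            d, b = _bump_spec(9.3, grid), _bump_spec(9.3, grid)
            d.power = d.power * (1 + 0.1 * rng.random(d.power.shape))
            drug[s], base[s] = [d], [b]
        _, ch, mean = power_change(drug, base)
        np.testing.assert_allclose(mean, np.nanmean(ch, axis=1))

    def test_band_topography_shape(self, grid):
        rng = np.random.default_rng(1)
        ch = rng.normal(0, 1, (5, 2, 41))
        topo = band_topography(ch, grid, 6.2, 8.7)
        assert topo.shape == (5, 2)


class TestNullPipeline:
    def test_grand_mean_change_near_zero_without_effect(self):
        """Full chain on a no-effect study (12 subjects, 4 recordings per
        condition, 220 s): grand-mean absolute relative-power change stays
        below 3%."""
        from neuropd.pipeline import analyze_eeg_study
        from neuropd.synth import EEGStudyTruth, gen_eeg_study

        study = gen_eeg_study(EEGStudyTruth(n_subjects=12, n_recordings=4,
                                            seed=42))
        res = analyze_eeg_study(study, n_perm=200, seed=0)
        grand = np.nanmean(res["change"], axis=0)
        assert np.nanmean(np.abs(grand)) < 3.0

    def test_parseval_power_tracks_band_variance(self, grid):
        """Total absolute wavelet power (summed over the grid in octave
        units) is proportional to the 2-64 Hz signal variance across
        realizations of varying amplitude."""
        from scipy import signal as sg
        rng = np.random.default_rng(9)
        sos = sg.butter(6, [2.0, 64.0], btype="bandpass", fs=256.0,
                        output="sos")
        totals, variances = [], []
        for k in range(12):
            amp = 1e-5 * (0.5 + rng.random())
            x = rng.normal(0, amp, (2, 256 * 60))
            spec = wavelet_power(_rec(x), grid)
            totals.append(np.nansum(spec.channel_mean()) * grid.step_octaves)
            xb = sg.sosfiltfilt(sos, x, axis=1)
            variances.append(xb.var())
        r = np.corrcoef(totals, variances)[0, 1]
        assert r > 0.99
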