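"""RR estimators: spectral mask filter, envelope chain, peak search, Pan-Tompkins."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cecgkit as ck
from cecgkit.rr import SearchBand

from conftest import make_section

FS = 125.0


def tone(freq, fs=FS, seconds=16.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestFFTBandpass:
    def test_in_band_passthrough(self):
        x = tone(10.0)
        y = ck.fft_bandpass(x, FS)
        assert np.max(np.abs(y - x)) < 1e-6 * np.max(np.abs(x))

    def test_out_of_band_rejection(self):
        x = tone(30.0)
        y = ck.fft_bandpass(x, FS)
        assert np.max(np.abs(y)) < 1e-6 * np.max(np.abs(x))

    def test_mixture_keeps_only_in_band_component(self):
        y = ck.fft_bandpass(tone(10.0) + tone(30.0), FS)
        assert np.max(np.abs(y - tone(10.0))) < 1e-6

    def test_idempotent_and_linear(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        once = ck.fft_bandpass(x, FS)
        assert np.allclose(ck.fft_bandpass(once, FS), once, atol=1e-9)
        y = rng.normal(size=2000)
        both = ck.fft_bandpass(x + 2 * y, FS)
        assert np.allclose(both, ck.fft_bandpass(x, FS) + 2 * ck.fft_bandpass(y, FS),
                           atol=1e-9)

    def test_out_of_band_energy_suppressed(self):
        x = np.random.default_rng(1).normal(size=4096)
        y = ck.fft_bandpass(x, FS)
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(y.size, 1 / FS)
        out_band = spec[(freqs < 5) | (freqs > 15)]
        assert out_band.sum() < 1e-9 * spec.sum()

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ck.fft_bandpass(np.zeros(100), FS, 5, 70)


class TestEnvelopeChain:
    def test_constant_input_gives_zero_envelope(self):
        proc = ck.envelope_chain(np.full(500, 2.0), FS)
        assert np.all(proc.envelope == 0)
        assert proc.fs_eff == FS / 10

    @pytest.mark.parametrize("n", [30, 47, 100, 333])
    def test_output_length_formula(self, n):
        x = np.random.default_rng(n).normal(size=n)
        proc = ck.envelope_chain(x, FS)
        # independent enumeration of full 19-sample windows strided by 10
        count = 0
        start = 0
        while start + 19 <= n - 1:
            count += 1
            start += 10
        assert proc.envelope.size == count == (n - 1 - 19) // 10 + 1

    @given(st.integers(0, 2**32 - 1))
    def test_envelope_nonnegative(self, seed):
        x = np.random.default_rng(seed).normal(size=300)
        assert np.min(ck.envelope_chain(x, FS).envelope) >= 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ck.envelope_chain(np.zeros(19), FS)


class TestRRFromSpectrum:
    def test_single_tone_envelope(self):
        fs_eff = 12.5
        t = np.arange(int(40 * fs_eff)) / fs_eff
        env = 1.0 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
        est = ck.rr_from_spectrum(ck.ProcessedSection(env, fs_eff))
        assert est.rr == pytest.approx(1.000, abs=0.005)
        assert est.method == "fft"

    def test_against_dense_grid_search(self):
        fs_eff = 12.5
        t = np.arange(int(15 * fs_eff)) / fs_eff
        env = 1.0 + 0.5 * np.cos(2 * np.pi * 1.25 * t)
        est = ck.rr_from_spectrum(ck.ProcessedSection(env, fs_eff),
                                  freq_resolution=0.005)
        # oracle: explicit DTFT magnitude over a dense candidate grid
        grid = np.arange(0.84, 1.83, 0.0005)
        mags = [abs(np.sum(env * np.exp(-2j * np.pi * f * t))) for f in grid]
        f_oracle = grid[int(np.argmax(mags))]
        assert abs(est.peak_freq - f_oracle) <= 0.005
        assert est.rr == pytest.approx(0.800, abs=0.005)

    def test_tie_breaks_to_lowest_frequency(self):
        # a periodic impulse train has exactly equal-magnitude harmonics;
        # period 14 samples at 12.5 Hz puts 0.8929 and 1.7857 Hz in band,
        # so the tie must resolve to the lower one (the cardiac fundamental)
        fs_eff = 12.5
        env = np.zeros(350)
        env[::14] = 1.0
        est = ck.rr_from_spectrum(ck.ProcessedSection(env, fs_eff))
        assert est.peak_freq == pytest.approx(12.5 / 14, abs=1e-9)
        assert est.rr == pytest.approx(14 / 12.5, abs=1e-9)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="cardiac band"):
            ck.rr_from_spectrum(ck.ProcessedSection(np.zeros(100), 12.5))


class TestEstimateRRFFT:
    def test_section_level_recovery_at_60bpm(self):
        x, fs, _ = make_section(60)
        est = ck.estimate_rr_fft(x, fs)
        assert abs(est.rr - 1.0) <= 0.01

    def test_whole_signal_finer_resolution(self, clean_60bpm_recording):
        rec, _ = clean_60bpm_recording
        est = ck.estimate_rr_fft(rec.samples, rec.fs)
        assert abs(est.rr - 1.0) <= 0.005

    def test_band_edge_clamped(self):
        x, fs, _ = make_section(50)
        est = ck.estimate_rr_fft(x, fs)
        assert est.peak_freq >= SearchBand().lo

    @pytest.mark.parametrize("hr", range(50, 115, 5))
    def test_parameter_recovery_across_resting_range(self, hr):
        x, fs, _ = make_section(hr)
        est = ck.estimate_rr_fft(x, fs)
        rr_true = 60.0 / hr
        assert abs(est.rr - rr_true) / rr_true <= 0.01

    @pytest.mark.parametrize("scale", [1e-3, 0.5, 7.0, 1e4])
    def test_amplitude_scale_invariance(self, scale):
        x, fs, _ = make_section(72)
        a = ck.estimate_rr_fft(x, fs)
        b = ck.estimate_rr_fft(scale * x, fs)
        assert a.rr == b.rr


class TestDetectRPeaks:
    def test_clean_60bpm_peaks_match_truth(self, clean_60bpm_recording):
        rec, truth = clean_60bpm_recording
        peaks = ck.detect_r_peaks(rec.samples, rec.fs)
        assert abs(peaks.size - truth.r_peak_times.size) <= 1
        truth_idx = truth.r_peak_times * rec.fs
        for p in peaks:
            assert np.min(np.abs(truth_idx - p)) <= 1.0

    def test_all_zero_signal_gives_no_peaks(self):
        assert ck.detect_r_peaks(np.zeros(10 * 125), 125.0).size == 0

    def test_peak_count_80bpm_525s(self):
        truth = ck.gen_rr_series(
            ck.RRSeriesSpec(mean_hr=80, hr_sd=0, duration=525), seed=6)
        rec = ck.preprocess_recording(ck.synth_clean_ecg(truth, duration=526))
        peaks = ck.detect_r_peaks(rec.samples, rec.fs)
        assert truth.r_peak_times.size == 700
        assert abs(peaks.size - 700) <= 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ck.detect_r_peaks(np.zeros(125), 125.0)


class TestRRMeanFromPeaks:
    def test_uniform_spacing(self):
        est = ck.rr_mean_from_peaks(np.array([0, 125, 250]), 125.0)
        assert est.rr == 1.000
        assert est.method == "pt"

    def test_arithmetic_mean_of_intervals(self):
        est = ck.rr_mean_from_peaks(np.array([0, 100, 250]), 125.0)
        assert est.rr == pytest.approx(1.000)

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            ck.rr_mean_from_peaks(np.array([42]), 125.0)

    def test_truth_indices_reproduce_truth_mean_rr(self):
        truth = ck.gen_rr_series(
            ck.RRSeriesSpec(mean_hr=90, hr_sd=0, duration=60), seed=8)
        idx = np.round(truth.r_peak_times * 500).astype(int)
        est = ck.rr_mean_from_peaks(idx, 500.0)
        assert est.rr == pytest.approx(truth.mean_rr, abs=1.0 / 500)


class TestMethodAgreement:
    def test_fft_and_pt_agree_on_clean_recordings(self):
        spec = ck.RRSeriesSpec(mean_hr=None, hr_sd=0, duration=525)
        pairs = ck.gen_paired_dataset(3, spec, noise=ck.NoiseSpec.none(), seed=5)
        tab = ck.method_agreement([p.reference for p in pairs])
        assert tab["pct_diff"].mean() <= 1.0
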