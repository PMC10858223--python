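"""Wavelet band decomposition, band-power change, gamma epochs, CSD,
spectrogram gamma-peak statistics, wake scoring, and reference-channel
selection."""
import numpy as np
import pytest

import popsync as ps
from popsync.core import LFPRecording, SpikeTrainSet, SpikeUnit
from popsync.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from popsync.lfp import (
    band_power_change,
    compute_csd,
    detect_gamma_epochs,
    gamma_peak_shuffle_test,
    score_wake,
    select_reference_channel,
    spectrogram_gamma_peaks,
    wavelet_band,
)

FS = 1250.0


def _sine(freq, duration=60.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestWaveletBand:
    def test_pure_tone_dominant_frequency_and_phase_slope(self, gamma_decomp):
        d = gamma_decomp
        assert np.median(d.dominant_freq) == pytest.approx(40.0, rel=0.05)
        # unwrapped phase advances 2 pi x 40 per second, within 1%
        mid = slice(1000, 14000)
        slope = np.polyfit(d.times[mid], np.unwrap(d.phase[mid]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 40, rel=0.01)
        assert np.median(d.amplitude) == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_rejection(self):
        in_band = wavelet_band(_sine(40.0), FS, "gamma").amplitude.mean()
        out_band = wavelet_band(_sine(8.0), FS, "gamma").amplitude.mean()
        assert in_band / out_band >= 10.0

    def test_white_noise_no_dominant_persistence(self):
        rng = np.random.default_rng(0)
        d = wavelet_band(rng.standard_normal(int(60 * FS)), FS, "gamma")
        # dominant frequency bounces across the 8 bins instead of pinning
        _, counts = np.unique(d.dominant_freq, return_counts=True)
        assert counts.max() / counts.sum() < 0.5

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            wavelet_band(_sine(10, 2), 100.0, "gamma")
        with pytest.raises(InvalidParameterError):
            wavelet_band(_sine(10, 2), FS, "ripple")


class TestBandPowerChange:
    def test_closed_forms(self):
        pre = wavelet_band(_sine(40, 20), FS, "gamma")
        post2 = wavelet_band(_sine(40, 20, amp=2.0), FS, "gamma")
        post01 = wavelet_band(_sine(40, 20, amp=0.1), FS, "gamma")
        assert band_power_change(pre, pre) == pytest.approx(0.0)
        assert band_power_change(pre, post2) == pytest.approx(6.02, abs=0.1)
        assert band_power_change(pre, post01) == pytest.approx(-20.0, abs=0.1)


class TestGammaEpochs:
    @staticmethod
    def _bursty(n_bursts=25, noise=0.3, seed=5):
        rng = np.random.default_rng(seed)
        t = np.arange(int(110 * FS)) / FS
        x = noise * rng.standard_normal(t.size)
        starts = 2 + 4.0 * np.arange(n_bursts)
        for b in starts:
            m = (t >= b) & (t < b + 0.3)
            x[m] += 1.5 * np.sin(2 * np.pi * 45 * t[m])
        return x, starts

    def test_planted_burst_recovery(self):
        x, starts = self._bursty()
        ep, troughs = detect_gamma_epochs(wavelet_band(x, FS, "gamma"))
        assert abs(len(ep) - len(starts)) <= 1
        assert troughs.size == len(ep)
        # each trough lies within its epoch (pads allowed at the edges)
        for (a, b), tr in zip(ep.intervals, troughs):
            assert a - 0.05 <= tr <= b + 0.05

    def test_threshold_monotonicity(self):
        x, _ = self._bursty()
        d = wavelet_band(x, FS, "gamma")
        n2 = len(detect_gamma_epochs(d, threshold_sd=2)[0])
        n3 = len(detect_gamma_epochs(d, threshold_sd=3)[0])
        assert n3 <= n2

    def test_constant_signal_warns_no_epochs(self):
        d = wavelet_band(np.zeros(int(70 * FS)), FS, "gamma")
        with pytest.warns(UserWarning):
            ep, _ = detect_gamma_epochs(d)
        assert len(ep) == 0


class TestCSD:
    def test_linear_depth_field_zero(self):
        rec = LFPRecording(np.outer(np.arange(5.0), np.ones(2500)), FS, np.arange(5))
        csd = compute_csd(rec, [0.5, 1.0])
        assert np.abs(csd.values).max() == pytest.approx(0.0, abs=1e-12)

    def test_dipole_sign_flip_and_gamma_alternation(self):
        lfp = ps.synth.gen_laminar_lfp(5, 10, gamma_freq=40.0,
                                       dipole_channels=(1, 3), noise_sd=0.0, seed=1)
        csd = compute_csd(lfp, np.arange(1, 9, 0.5), half_window=0.05)
        # rows are channels 1..3; source and sink rows anti-phase
        src, mid, snk = csd.values
        j = np.argmax(np.abs(src))
        assert np.sign(src[j]) == -np.sign(snk[j])
        # alternation at the gamma period: autocorrelation minimum near 12.5 ms
        lag_samples = int(0.0125 * FS)
        ac = np.corrcoef(src[:-lag_samples], src[lag_samples:])[0, 1]
        assert ac < -0.8

    def test_single_alignment_is_plain_average(self):
        lfp = ps.synth.gen_laminar_lfp(4, 4, noise_sd=0.0, seed=0)
        one = compute_csd(lfp, [2.0])
        assert one.n_alignments == 1
        with pytest.raises(InvalidInputError):
            compute_csd(lfp, [])
        rec2 = LFPRecording(np.zeros((2, 100)), FS, [0, 1])
        with pytest.raises(InvalidInputError):
            compute_csd(rec2, [0.01])


class TestSpectrogramGammaPeak:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(1)
        segs = [rng.standard_normal(2500) for _ in range(10)]
        peaks = spectrogram_gamma_peaks(segs)
        _, p = gamma_peak_shuffle_test(peaks, peaks, n_shuffles=200, seed=0)
        assert p > 0.5

    def test_planted_gamma_component_detected(self):
        rng = np.random.default_rng(2)
        t = np.arange(2500) / FS
        a = [rng.standard_normal(2500) for _ in range(30)]
        b = [rng.standard_normal(2500) + 0.5 * np.sin(2 * np.pi * 40 * t)
             for _ in range(30)]
        d, p = gamma_peak_shuffle_test(
            spectrogram_gamma_peaks(a), spectrogram_gamma_peaks(b),
            n_shuffles=1000, seed=3,
        )
        assert d > 0 and p < 0.001 + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            spectrogram_gamma_peaks([np.zeros(500)])
        with pytest.raises(InsufficientDataError):
            gamma_peak_shuffle_test([1.0], [2.0])

    def test_null_calibration_reduced(self):
        # permutation test attains ~nominal type-I error (0.05 level)
        rng = np.random.default_rng(4)
        rejections = 0
        n_runs = 200
        for _ in range(n_runs):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            _, p = gamma_peak_shuffle_test(a, b, n_shuffles=99, seed=int(rng.integers(1 << 30)))
            rejections += p < 0.05
        assert rejections / n_runs <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_runs)


class TestWakeScoring:
    def test_planted_state_blocks(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(120 * FS)) / FS
        theta_on = (t // 30) % 2 == 0
        x = np.where(theta_on, np.sin(2 * np.pi * 8 * t),
                     3 * np.sin(2 * np.pi * 2 * t))
        x += 0.1 * rng.standard_normal(t.size)
        with pytest.warns(UserWarning):
            wake = score_wake(x, FS)
        expected = np.array([[0, 30], [60, 90]])
        assert len(wake) == 2
        assert np.abs(wake.intervals - expected).max() <= 2.0

    def test_constant_high_movement_all_wake(self):
        rng = np.random.default_rng(1)
        x = 3 * np.sin(2 * np.pi * 2 * np.arange(int(40 * FS)) / FS)
        move = np.r_[np.zeros(100), 5 + rng.standard_normal(int(40 * FS) - 100)]
        wake = score_wake(x, FS, movement=move)
        assert wake.total_duration >= 35.0


class TestReferenceChannel:
    @staticmethod
    def _spikes(peak_channels, labels):
        return SpikeTrainSet([
            SpikeUnit(f"u{i}", np.array([1.0]), label=l, peak_channel=c)
            for i, (c, l) in enumerate(zip(peak_channels, labels))
        ])

    def test_argmax_by_e_count(self):
        lfp = ps.synth.gen_laminar_lfp(3, 2, dipole_channels=(0, 2),
                                       noise_sd=0.1, seed=0)
        s = self._spikes([0, 1, 1, 1, 2, 1], ["E"] * 5 + ["I"])
        assert select_reference_channel(s, lfp) == 1

    def test_tie_broken_by_gamma_power(self):
        # channel 1 carries the oscillation (plus noise); channel 0/2 noise
        lfp = ps.synth.gen_laminar_lfp(4, 4, dipole_channels=(1, 2),
                                       noise_sd=0.05, seed=2)
        s = self._spikes([1, 2, 1, 2], ["E"] * 4)
        assert select_reference_channel(s, lfp) in (1, 2)
        got = select_reference_channel(s, lfp)
        a1 = ps.lfp.wavelet_band(lfp.samples[1], lfp.fs, "gamma").amplitude.mean()
        a2 = ps.lfp.wavelet_band(lfp.samples[2], lfp.fs, "gamma").amplitude.mean()
        assert got == (1 if a1 >= a2 else 2)

    def test_no_e_units_rejected(self):
        lfp = ps.synth.gen_laminar_lfp(3, 2, dipole_channels=(0, 2), seed=0)
        with pytest.raises(InvalidInputError):
            select_reference_channel(self._spikes([0, 1], ["I", "I"]), lfp)
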