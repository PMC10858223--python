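"""Inhalation detection, evoked rates, the cumulative Poisson-surprise
statistic with shuffle FDR, and signal/noise correlations."""
import numpy as np
import pandas as pd
import pytest

import popsync as ps
from popsync.core import RespirationTrace, TrialTable
from popsync.errors import InsufficientDataError, InvalidInputError
from popsync.odor import (
    _cumulative_surprise,
    detect_inhalation_onsets,
    evoked_rates,
    noise_correlation,
    session_surprise,
    signal_correlation,
    surprise_analysis,
)


class TestInhalationOnsets:
    def test_sinusoid_count_and_spacing(self):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        resp = RespirationTrace(np.sin(2 * np.pi * 3.0 * t), fs)
        onsets = detect_inhalation_onsets(resp)
        # negative-going crossings of a 3 Hz sinusoid: one per 1/3 s
        assert 28 <= onsets.size <= 30
        # interior spacings exact; filter edge transients spare the ends
        assert np.allclose(np.diff(onsets)[1:-1], 1 / 3, atol=0.005)

    def test_recovery_against_generator_truth(self):
        s = ps.synth.gen_odor_session(2, n_trials_per_odor=3, seed=4)
        onsets = detect_inhalation_onsets(s.respiration)
        truth = s.truth.inhalation_onsets
        assert onsets.size == truth.size
        assert np.abs(onsets - truth).max() <= 0.020

    def test_flat_and_short_traces(self):
        with pytest.raises(InvalidInputError):
            detect_inhalation_onsets(RespirationTrace(np.zeros(10), 200.0))
        with pytest.warns(UserWarning):
            got = detect_inhalation_onsets(RespirationTrace(np.zeros(1000), 200.0))
        assert got.size == 0


def _mini_trials(n=6, period=22.0, lead=10.0):
    rows = []
    for k in range(n):
        od = "oil" if k % 3 == 2 else ("a" if k % 3 == 0 else "b")
        rows.append(dict(trial_id=f"t{k}", odorant="mineral_oil" if od == "oil" else od,
                         concentration=0.1, onset=lead + k * period,
                         offset=lead + k * period + 2.0,
                         is_control=od == "oil"))
    return TrialTable(pd.DataFrame(rows))


class TestEvokedRates:
    def test_silent_unit_all_zero(self):
        trials = _mini_trials()
        onsets = np.arange(0.2, 150, 1 / 3)
        df = evoked_rates(np.empty(0), trials, onsets)
        assert (df["odor_rate"] == 0).all() and (df["baseline_rate"] == 0).all()

    def test_planted_gain_ratio(self):
        s = ps.synth.gen_odor_session(1, n_trials_per_odor=30,
                                      odorants=["a"], response_gain={0: 3.0},
                                      base_rate=8.0, seed=6)
        onsets = detect_inhalation_onsets(s.respiration)
        df = evoked_rates(s.spikes[0].spike_times, s.trials, onsets)
        odor = df[~df["is_control"]]
        ratio = odor["odor_rate"].mean() / odor["baseline_rate"].mean()
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_window_halfopen_boundary(self):
        trials = _mini_trials(n=3)
        onsets = np.array([10.1, 7.5])  # odor inhale, baseline breath
        onsets.sort()
        # spike exactly at window stop is excluded
        df = evoked_rates(np.array([10.1 + 0.350]), trials, onsets)
        assert df.loc[0, "odor_rate"] == 0.0


class TestSurprise:
    def test_additivity_per_bin(self):
        rng = np.random.default_rng(0)
        oc = rng.poisson(1.0, (20, 35))
        bc = rng.poisson(1.0, (20, 35))
        act, inh, s_bins = _cumulative_surprise(oc, bc)
        assert act == pytest.approx(s_bins.sum())

    def test_null_unit_not_significant(self):
        s = ps.synth.gen_odor_session(3, n_trials_per_odor=15,
                                      odorants=["a", "b"], seed=9)
        onsets = detect_inhalation_onsets(s.respiration)
        res = surprise_analysis(s.spikes[0].spike_times, s.trials, onsets, seed=1)
        assert len(res) == 2
        assert not any(r.significant for r in res)
        assert all(r.shuffle_distribution.size == 100 for r in res)

    def test_planted_responder_detected_activated(self):
        hits = 0
        for seed in range(4):
            s = ps.synth.gen_odor_session(
                6, n_trials_per_odor=30, odorants=["a", "b"],
                response_gain={0: 3.0}, seed=20 + seed,
            )
            onsets = detect_inhalation_onsets(s.respiration)
            df = session_surprise(s.spikes, s.trials, onsets, seed=seed)
            hit = df[(df.unit_id == "U000") & df.significant]
            if len(hit) == 2 and (hit["direction"] == "activated").all():
                hits += 1
        assert hits >= 3

    def test_significance_iff_above_threshold(self):
        s = ps.synth.gen_odor_session(2, n_trials_per_odor=10,
                                      odorants=["a"], seed=3)
        onsets = detect_inhalation_onsets(s.respiration)
        for r in surprise_analysis(s.spikes[0].spike_times, s.trials, onsets, seed=0):
            assert r.significant == (r.cumulative_surprise > r.threshold)


class TestCorrelations:
    def test_signal_correlation_trivials(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        assert signal_correlation(v, v) == pytest.approx(1.0)
        assert signal_correlation(v, -v) == pytest.approx(-1.0)
        # affine invariance
        assert signal_correlation(2 * v + 7, v) == pytest.approx(1.0)
        with pytest.raises(InsufficientDataError):
            signal_correlation(np.ones(4), v + 1)

    def test_signal_correlation_null_spread(self):
        rng = np.random.default_rng(1)
        rs = [
            signal_correlation(rng.standard_normal(35), rng.standard_normal(35))
            for _ in range(400)
        ]
        assert np.mean(rs) == pytest.approx(0.0, abs=0.02)
        assert np.std(rs) == pytest.approx(1 / np.sqrt(34), rel=0.2)

    def test_noise_correlation_trivials(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((20, 10))
        assert noise_correlation(a, a.copy()) == pytest.approx(1.0)
        b = rng.standard_normal((20, 10))
        assert abs(noise_correlation(a, b)) <= 0.12
        with pytest.raises(InsufficientDataError):
            noise_correlation(a[:1], b[:1])

    @staticmethod
    def _trial_count_matrices(session):
        # bins straddle the response window so a shared gain shapes the
        # within-trial profile (a flat profile's common gain cancels in the
        # per-trial Pearson, which removes each trial's mean)
        win = session.truth.extras["response_windows"]
        return [
            np.array([
                np.histogram(u.spike_times, bins=10, range=(a - 0.2, a + 0.5))[0]
                for a, _ in win
            ])
            for u in session.spikes
        ]

    def test_shared_trial_gain_recovered_positive(self):
        # shared per-trial gain plants positive noise correlation
        s = ps.synth.gen_odor_session(
            2, n_trials_per_odor=30, odorants=["a"], base_rate=20.0,
            response_gain={0: 2.0, 1: 2.0}, shared_gain_sd=0.5, seed=12,
        )
        ma, mb = self._trial_count_matrices(s)
        r = noise_correlation(ma, mb)
        s0 = ps.synth.gen_odor_session(
            2, n_trials_per_odor=30, odorants=["a"], base_rate=20.0,
            response_gain={0: 2.0, 1: 2.0}, shared_gain_sd=0.0, seed=12,
        )
        ma0, mb0 = self._trial_count_matrices(s0)
        r0 = noise_correlation(ma0, mb0)
        assert r > r0 + 0.1
        assert abs(r0) < 0.1
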