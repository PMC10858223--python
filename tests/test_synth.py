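"""Ground-truth generators: determinism, planted-parameter consistency,
and the closed-form circular statistics of locked spiking."""
import numpy as np
import pytest
from scipy.special import i0, i1
from scipy.stats import poisson

import popsync as ps
from popsync.errors import (
    InvalidInputError,
    InvalidParameterError,
)


class TestSpikeSession:
    def test_determinism_byte_identical(self):
        a = ps.synth.gen_spike_session(5, 1, duration=30, seed=1)
        b = ps.synth.gen_spike_session(5, 1, duration=30, seed=1)
        for ua, ub in zip(a.spikes, b.spikes):
            assert ua.spike_times.tobytes() == ub.spike_times.tobytes()
        assert a.truth.popevent_intervals.tobytes() == b.truth.popevent_intervals.tobytes()

    def test_no_events_when_rate_zero(self):
        s = ps.synth.gen_spike_session(5, 0, duration=60, popevent_rate=0.0, seed=2)
        assert s.truth.popevent_intervals.size == 0

    def test_planted_count_within_poisson_ci(self):
        # 0.4 events/s x 600 s = 240 expected; Poisson 95% CI
        s = ps.synth.gen_spike_session(12, 0, duration=600, popevent_rate=0.4,
                                       popevent_gain=5.0, seed=7)
        lo, hi = poisson.ppf([0.025, 0.975], 240)
        assert lo <= s.truth.popevent_intervals.shape[0] <= hi

    def test_pooled_rate_within_3_poisson_sd(self):
        s = ps.synth.gen_spike_session(10, 0, duration=300, base_rate=2.0,
                                       popevent_rate=0.0, seed=3)
        n = sum(u.n_spikes for u in s.spikes)
        expected = 10 * 2.0 * 300
        assert abs(n - expected) <= 3 * np.sqrt(expected)

    def test_gain_elevates_rate_inside_events(self):
        s = ps.synth.gen_spike_session(12, 0, duration=600, popevent_gain=5.0, seed=4)
        ev = ps.EventIntervalSet(s.truth.popevent_intervals)
        t_in = ev.total_duration
        inside = sum(ev.contains(u.spike_times).sum() for u in s.spikes)
        outside = sum(u.n_spikes for u in s.spikes) - inside
        rate_in = inside / (12 * t_in)
        rate_out = outside / (12 * (600 - t_in))
        assert rate_in == pytest.approx(10.0, rel=0.1)
        assert rate_out == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("kwargs", [
        dict(n_excitatory=0), dict(n_excitatory=5, duration=-1),
        dict(n_excitatory=5, base_rate=-2), dict(n_excitatory=5, popevent_gain=0.5),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ps.synth.gen_spike_session(**kwargs)


class TestLockedSpikes:
    def test_uniform_limit_kappa_zero(self, gamma_decomp):
        t = ps.synth.gen_locked_spikes(gamma_decomp.phase, 250.0, 0.0, 0.0,
                                       n_spikes=1000, seed=1)
        ph = ps.phaselock.spike_phases(t, gamma_decomp)
        assert ps.phaselock.rayleigh_test(ph) > 0.05

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_resultant_matches_bessel_ratio(self, gamma_decomp, kappa):
        # closed form: E[R] -> I1(kappa)/I0(kappa) as n grows
        t = ps.synth.gen_locked_spikes(gamma_decomp.phase, 250.0, mu=0.7,
                                       kappa=kappa, n_spikes=5000, seed=11)
        ph = ps.phaselock.spike_phases(t, gamma_decomp)
        R = ps.phaselock.phase_lock_stats(ph).resultant_length
        assert R == pytest.approx(i1(kappa) / i0(kappa), abs=0.03)

    def test_zero_spikes_and_empty_phase(self):
        assert ps.synth.gen_locked_spikes(np.zeros(100), 250.0, 0.0, 1.0, 0).size == 0
        with pytest.raises(InvalidInputError):
            ps.synth.gen_locked_spikes(np.empty(0), 250.0, 0.0, 1.0, 10)


class TestLaminarLFP:
    def test_profile_sign_reversal(self):
        lfp = ps.synth.gen_laminar_lfp(5, 2.0, dipole_channels=(1, 3),
                                       noise_sd=0.0, seed=0)
        # source and sink channels anti-phase: strongly negative correlation
        c = np.corrcoef(lfp.samples[1], lfp.samples[3])[0, 1]
        assert c == pytest.approx(-1.0, abs=1e-9)

    def test_zero_amplitude_flat(self):
        lfp = ps.synth.gen_laminar_lfp(4, 1.0, amplitude=0.0, noise_sd=0.0, seed=0)
        assert np.all(lfp.samples == 0)

    def test_seed_determinism(self):
        a = ps.synth.gen_laminar_lfp(4, 1.0, noise_sd=0.3, seed=9)
        b = ps.synth.gen_laminar_lfp(4, 1.0, noise_sd=0.3, seed=9)
        assert a.samples.tobytes() == b.samples.tobytes()

    def test_too_few_channels(self):
        with pytest.raises(InvalidParameterError):
            ps.synth.gen_laminar_lfp(2, 1.0)
        with pytest.raises(InvalidParameterError):
            ps.synth.gen_laminar_lfp(5, 1.0, dipole_channels=(2, 2))


class TestOdorSession:
    def test_no_responders_by_default(self):
        s = ps.synth.gen_odor_session(4, n_trials_per_odor=3, seed=1)
        assert s.truth.odor_effects == {}

    def test_truth_marks_responders(self):
        s = ps.synth.gen_odor_session(4, n_trials_per_odor=3,
                                      response_gain={0: 3.0}, seed=1)
        assert all(uid == "U000" for uid, _ in s.truth.odor_effects)
        assert set(s.truth.odor_effects.values()) == {3.0}

    def test_reserved_control_label_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.synth.gen_odor_session(4, odorants=["mineral_oil"])

    def test_schedule_counts_and_spacing(self):
        s = ps.synth.gen_odor_session(2, n_trials_per_odor=5,
                                      odorants=["a", "b"], seed=2)
        df = s.trials.df
        assert len(df) == 15  # 2 odorants + control, 5 each
        assert (df.groupby("odorant").size() == 5).all()
        assert np.allclose(df["offset"] - df["onset"], 2.0)
        assert np.all(np.diff(df["onset"]) == 22.0)


class TestPhotometry:
    def test_determinism(self):
        a, _ = ps.synth.gen_photometry(duration=60, seed=5)
        b, _ = ps.synth.gen_photometry(duration=60, seed=5)
        assert a.raw_f.tobytes() == b.raw_f.tobytes()

    def test_sharp_onset_and_decay(self):
        tr, truth = ps.synth.gen_photometry(duration=60, event_rate=0.2,
                                            amplitude_sd_units=20, noise_sd=0.01,
                                            seed=2)
        t0 = truth.calcium_event_times[0]
        i0_ = int(t0 * tr.fs)
        peak = tr.raw_f[i0_:i0_ + int(0.05 * tr.fs)].max()
        base = 100.0
        # rise completes within 50 ms
        assert peak - base > 0.9 * 20 * 0.01
        # decays to < half within 2 tau
        later = tr.raw_f[i0_ + int(0.65 * tr.fs)]
        assert later - base < 0.55 * (peak - base)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            ps.synth.gen_photometry(event_rate=-1)
        with pytest.raises(InvalidParameterError):
            ps.synth.gen_photometry(amplitude_sd_units=0)
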