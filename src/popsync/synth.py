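"""Synthetic sessions with planted ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — transient population co-activations in Poisson spiking, a
laminar gamma dipole, von Mises phase-locked spiking, inhalation-locked
odor responses with a shared trial gain, calcium transients over drifting
fluorescence — and records every planted parameter in a
:class:`~popsync.core.GroundTruth` so recovery can be asserted.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed and parameters reproduce a byte-identical session.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import (
    GroundTruth,
    LFPRecording,
    PhotometryTrace,
    RespirationTrace,
    SpikeTrainSet,
    SpikeUnit,
    SyntheticSession,
    TrialTable,
)
from .errors import InvalidInputError, InvalidParameterError

import pandas as pd

__all__ = [
    "gen_spike_session",
    "gen_locked_spikes",
    "gen_laminar_lfp",
    "gen_odor_session",
    "gen_photometry",
]

CONTROL_ODORANT = "mineral_oil"


def _renewal_events(rng, duration, rate, event_duration, min_gap):
    """Non-overlapping event intervals at ~`rate` events/s.

    Hard-core renewal process: inter-onset interval = (event_duration +
    min_gap) + Exp with mean chosen so the mean onset rate equals `rate`.
    """
    dead = event_duration + min_gap
    if rate <= 0:
        return np.empty((0, 2))
    mean_iei = 1.0 / rate
    if mean_iei <= dead:
        raise InvalidParameterError(
            f"popevent_rate={rate} too high for duration {event_duration}s + gap"
        )
    exp_mean = mean_iei - dead
    starts = []
    t = rng.uniform(0.0, mean_iei)
    while t + event_duration < duration:
        starts.append(t)
        t += dead + rng.exponential(exp_mean)
    iv = np.array([[s, s + event_duration] for s in starts]).reshape(-1, 2)
    return iv


def _piecewise_poisson(rng, duration, base_rate, windows, window_rates):
    """Exact sampling of an inhomogeneous Poisson train with a piecewise-
    constant rate: `base_rate` everywhere except inside `windows` (an (n,2)
    array of non-overlapping sorted intervals) where the rate is the
    corresponding entry of `window_rates`.

    Uses thinning at the maximum rate so the draw order — hence the result —
    is independent of how the windows partition time.
    """
    windows = np.asarray(windows, dtype=float).reshape(-1, 2)
    window_rates = np.asarray(window_rates, dtype=float)
    rates = np.concatenate(([base_rate], window_rates)) if windows.size else np.array(
        [base_rate]
    )
    max_rate = float(rates.max(initial=0.0))
    if max_rate == 0.0:
        return np.empty(0)
    n = rng.poisson(max_rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    u = rng.uniform(0.0, 1.0, size=n)
    rate_at = np.full(n, base_rate)
    if windows.size:
        idx = np.searchsorted(windows[:, 0], t, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(n, dtype=bool)
        inside[ok] = t[ok] < windows[idx[ok], 1]
        rate_at[inside] = window_rates[idx[inside]]
    return t[u * max_rate < rate_at]


def gen_spike_session(
    n_excitatory: int,
    n_inhibitory: int = 0,
    duration: float = 600.0,
    base_rate: float = 2.0,
    popevent_rate: float = 0.4,
    popevent_duration: float = 0.15,
    popevent_gain: float = 5.0,
    seed: int = 0,
    popevent_intervals: Optional[np.ndarray] = None,
) -> SyntheticSession:
    """Poisson E/I spiking with planted synchronous population events.

    During each planted event every excitatory unit's rate is multiplied
    by ``popevent_gain``; inhibitory units spike at ``base_rate``
    throughout. Pass ``popevent_intervals`` to plant explicit intervals
    (e.g. adversarial durations) instead of drawing them at
    ``popevent_rate``.
    """
    if n_excitatory < 1:
        raise InvalidParameterError("need at least one excitatory unit")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if base_rate < 0 or popevent_rate < 0:
        raise InvalidParameterError("rates must be non-negative")
    if popevent_gain < 1:
        raise InvalidParameterError("popevent_gain must be >= 1")

    rng = np.random.default_rng(seed)
    if popevent_intervals is not None:
        events = np.asarray(popevent_intervals, dtype=float).reshape(-1, 2)
    else:
        events = _renewal_events(rng, duration, popevent_rate, popevent_duration, 0.1)

    units = []
    base_rates = {}
    for i in range(n_excitatory):
        uid = f"E{i:03d}"
        t = _piecewise_poisson(
            rng, duration, base_rate, events,
            np.full(events.shape[0], base_rate * popevent_gain),
        )
        units.append(SpikeUnit(uid, t, label="E"))
        base_rates[uid] = base_rate
    for i in range(n_inhibitory):
        uid = f"I{i:03d}"
        t = _piecewise_poisson(rng, duration, base_rate, np.empty((0, 2)), np.empty(0))
        units.append(SpikeUnit(uid, t, label="I"))
        base_rates[uid] = base_rate

    truth = GroundTruth(
        seed=seed,
        popevent_intervals=events,
        popevent_rate=popevent_rate,
        unit_base_rates=base_rates,
        extras={"popevent_gain": popevent_gain, "popevent_duration": popevent_duration},
    )
    return SyntheticSession(truth=truth, duration=duration, spikes=SpikeTrainSet(units))


def gen_locked_spikes(
    phase: np.ndarray,
    fs: float,
    mu: float,
    kappa: float,
    n_spikes: int,
    seed: int = 0,
) -> np.ndarray:
    """Spike times whose phases (read from ``phase`` at the nearest sample)
    follow a von Mises(mu, kappa) distribution.

    Rejection sampling: candidate times are uniform over the series and
    accepted in proportion to the von Mises density of the local phase, so
    any oscillation whose phase sweeps uniformly yields exactly the target
    circular law. ``kappa=0`` reduces to uniform spiking.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.size == 0:
        raise InvalidInputError("empty phase series")
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if n_spikes == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    accepted = []
    n_left = n_spikes
    while n_left > 0:
        m = max(64, int(n_left / max(np.exp(-2 * kappa), 1e-3)))
        m = min(m, 4 * n_spikes + 1000)
        idx = rng.integers(0, phase.size, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        # density ratio to the max, exp(kappa*(cos(theta-mu)-1))
        keep = u < np.exp(kappa * (np.cos(phase[idx] - mu) - 1.0))
        accepted.append(idx[keep][:n_left])
        n_left -= int(min(keep.sum(), n_left))
    times = np.concatenate(accepted) / fs
    return np.sort(times)


def gen_laminar_lfp(
    n_channels: int,
    duration: float,
    gamma_freq: float = 40.0,
    dipole_channels: tuple = (1, 3),
    noise_sd: float = 0.1,
    seed: int = 0,
    fs: float = 1250.0,
    amplitude: float = 1.0,
    burst_rate: float = 0.0,
    burst_duration: float = 0.3,
) -> LFPRecording:
    """Laminar LFP with a gamma dipole: the oscillation's amplitude profile
    runs linearly from +amplitude at the source channel to -amplitude at the
    sink, so the field reverses sign between them — the configuration a CSD
    map must resolve into an alternating sink/source pair.

    With ``burst_rate`` > 0 the oscillation is gated into discrete
    ``burst_duration`` bursts at that rate (for testing gamma-epoch
    detection and epoch-aligned CSD); by default it runs continuously.
    """
    if n_channels < 3:
        raise InvalidParameterError("need at least 3 channels for a laminar profile")
    src, snk = dipole_channels
    if src == snk:
        raise InvalidParameterError("source and sink must differ")
    if not (0 <= src < n_channels and 0 <= snk < n_channels):
        raise InvalidParameterError("dipole channels out of range")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    osc = np.sin(2 * np.pi * gamma_freq * t)
    if burst_rate > 0:
        gate = np.zeros(n)
        for b0, b1 in _renewal_events(rng, duration, burst_rate, burst_duration, 0.2):
            gate[int(b0 * fs) : int(b1 * fs)] = 1.0
        osc = osc * gate

    lo, hi = (src, snk) if src < snk else (snk, src)
    profile = np.zeros(n_channels)
    span = np.linspace(1.0, -1.0, hi - lo + 1)
    if src > snk:
        span = span[::-1]
    profile[lo : hi + 1] = span
    samples = amplitude * profile[:, None] * osc[None, :]
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)
    return LFPRecording(
        samples=samples,
        fs=fs,
        channel_depths=np.arange(n_channels, dtype=float),
    )


def _gen_respiration(rng, duration, fs, freq, jitter_frac=0.1):
    """Sinusoidal pressure with cycle-to-cycle jittered period.

    Inhalation onset := negative-going zero crossing (phase passes pi).
    Returns (pressure, onset_times).
    """
    n = int(round(duration * fs))
    # draw per-cycle frequencies, integrate phase
    mean_period = 1.0 / freq
    t_cycle = 0.0
    boundaries = [0.0]
    while t_cycle < duration:
        period = mean_period * (1.0 + jitter_frac * rng.standard_normal())
        period = max(period, 0.3 * mean_period)
        t_cycle += period
        boundaries.append(t_cycle)
    boundaries = np.array(boundaries)
    t = np.arange(n) / fs
    cyc = np.searchsorted(boundaries, t, side="right") - 1
    cyc = np.clip(cyc, 0, boundaries.size - 2)
    frac = (t - boundaries[cyc]) / (boundaries[cyc + 1] - boundaries[cyc])
    pressure = np.sin(2 * np.pi * frac)
    onsets = boundaries[:-1] + 0.5 * (boundaries[1:] - boundaries[:-1])
    onsets = onsets[onsets < duration]
    return pressure, onsets


def gen_odor_session(
    n_units: int,
    n_trials_per_odor: int = 30,
    odorants: Sequence[str] = ("odorA", "odorB"),
    response_gain=None,
    shared_gain_sd: float = 0.0,
    seed: int = 0,
    base_rate: float = 2.0,
    trial_duration: float = 2.0,
    inter_stimulus: float = 20.0,
    response_window: float = 0.35,
    resp_freq: float = 3.0,
    resp_fs: float = 200.0,
    include_control: bool = True,
) -> SyntheticSession:
    """Olfactometry session: odorants presented ``n_trials_per_odor`` times
    for ``trial_duration`` s with an ``inter_stimulus`` gap, a ~3 Hz
    jitter-period respiration trace, and responsive units whose rate is
    multiplied by their gain for ``response_window`` s after the first
    inhalation in each (non-control) odor.

    ``response_gain`` maps unit index -> multiplicative gain (default: all
    1, i.e. no responders). A shared per-trial gain with SD
    ``shared_gain_sd`` scales every unit's response window in the same
    trial, planting positive noise correlation.
    """
    if n_trials_per_odor < 2:
        raise InvalidParameterError("need at least 2 trials per odorant")
    odorants = list(odorants)
    if CONTROL_ODORANT in odorants:
        raise InvalidParameterError(
            f"{CONTROL_ODORANT!r} is reserved for the control; rename the odorant"
        )
    if len(set(odorants)) != len(odorants):
        raise InvalidParameterError("duplicate odorant labels")
    gains = dict(response_gain or {})
    rng = np.random.default_rng(seed)

    labels = odorants + ([CONTROL_ODORANT] if include_control else [])
    schedule = np.repeat(np.arange(len(labels)), n_trials_per_odor)
    rng.shuffle(schedule)
    lead_in = 10.0
    period = trial_duration + inter_stimulus
    onsets = lead_in + np.arange(schedule.size) * period
    duration = float(onsets[-1] + trial_duration + inter_stimulus)

    rows = []
    for k, (oi, on) in enumerate(zip(schedule, onsets)):
        rows.append(
            dict(
                trial_id=f"t{k:04d}",
                odorant=labels[oi],
                concentration=0.1,
                onset=float(on),
                offset=float(on + trial_duration),
                is_control=labels[oi] == CONTROL_ODORANT,
            )
        )
    trials = TrialTable(pd.DataFrame(rows))

    pressure, inh_onsets = _gen_respiration(rng, duration, resp_fs, resp_freq)
    respiration = RespirationTrace(pressure=pressure, fs=resp_fs)

    # response window per non-control trial: [first inhalation >= onset, +350 ms)
    resp_windows = []
    trial_gain = []
    for row in trials.df.itertuples():
        if row.is_control:
            continue
        after = inh_onsets[inh_onsets >= row.onset]
        if after.size == 0 or after[0] >= row.offset:
            continue
        g = 1.0 + shared_gain_sd * rng.standard_normal() if shared_gain_sd > 0 else 1.0
        resp_windows.append((after[0], after[0] + response_window))
        trial_gain.append(max(g, 0.0))
    resp_windows = np.array(resp_windows).reshape(-1, 2)
    trial_gain = np.array(trial_gain)

    units = []
    base_rates = {}
    odor_effects = {}
    for i in range(n_units):
        uid = f"U{i:03d}"
        g_unit = float(gains.get(i, 1.0))
        rates = base_rate * g_unit * trial_gain if resp_windows.size else np.empty(0)
        t = _piecewise_poisson(rng, duration, base_rate, resp_windows, rates)
        units.append(SpikeUnit(uid, t, label="E"))
        base_rates[uid] = base_rate
        if g_unit != 1.0:
            for od in odorants:
                odor_effects[(uid, od)] = g_unit

    truth = GroundTruth(
        seed=seed,
        unit_base_rates=base_rates,
        odor_effects=odor_effects,
        inhalation_onsets=inh_onsets,
        extras={
            "shared_gain_sd": shared_gain_sd,
            "response_window": response_window,
            "response_windows": resp_windows,
        },
    )
    return SyntheticSession(
        truth=truth,
        duration=duration,
        spikes=SpikeTrainSet(units),
        respiration=respiration,
        trials=trials,
    )


def gen_photometry(
    duration: float = 600.0,
    event_rate: float = 0.33,
    amplitude_sd_units: float = 6.0,
    noise_sd: float = 1.0,
    drift: float = 0.0,
    seed: int = 0,
    fs: float = 1000.0,
    baseline_f: float = 100.0,
    rise_time: float = 0.02,
    decay_tau: float = 0.3,
) -> tuple[PhotometryTrace, GroundTruth]:
    """Fluorescence trace with stereotyped calcium transients: linear rise
    over ``rise_time`` (sharp onset) and exponential decay with time
    constant ``decay_tau``, amplitude ``amplitude_sd_units`` times the
    noise SD, over Gaussian noise (band-limited so the pipeline's 20 ms
    smoothing leaves its SD nearly unchanged) plus optional linear drift.
    """
    if amplitude_sd_units <= 0:
        raise InvalidParameterError("amplitude_sd_units must be positive")
    if event_rate < 0:
        raise InvalidParameterError("event_rate must be non-negative")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # noise low-passed at ~15 Hz keeps its SD through 20 ms smoothing
    from scipy.ndimage import gaussian_filter1d

    noise = rng.standard_normal(n)
    noise = gaussian_filter1d(noise, sigma=0.01 * fs)
    noise *= noise_sd / noise.std()

    f = baseline_f + drift * t + noise

    min_gap = 5 * decay_tau  # transients must not stack
    events = _renewal_events(rng, duration, event_rate, 0.0, min_gap)
    event_times = events[:, 0] if events.size else np.empty(0)

    if event_times.size:
        kernel_len = int((rise_time + 6 * decay_tau) * fs)
        kt = np.arange(kernel_len) / fs
        kernel = np.where(
            kt < rise_time,
            kt / rise_time,
            np.exp(-(kt - rise_time) / decay_tau),
        )
        amp = amplitude_sd_units * noise_sd
        for et in event_times:
            i0 = int(round(et * fs))
            i1 = min(i0 + kernel_len, n)
            f[i0:i1] += amp * kernel[: i1 - i0]

    trace = PhotometryTrace(raw_f=f, fs=fs)
    truth = GroundTruth(
        seed=seed,
        calcium_event_times=event_times,
        calcium_event_amplitude=amplitude_sd_units,
        extras={"noise_sd": noise_sd, "drift": drift, "event_rate": event_rate},
    )
    return trace, truth
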