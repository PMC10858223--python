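"""Wavelet band analysis of LFP: band decomposition on a 4 ms grid,
band-power change, gamma-epoch detection, current source density,
Hamming-spectrogram gamma-peak statistics, reference-channel selection,
and automatic wake scoring.

Band decomposition uses a complex Morlet wavelet (omega0 = 6) at 8
log-spaced center frequencies within the band; at every 4 ms grid point
the phase and amplitude are read from the frequency bin with maximal
power at that instant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EventIntervalSet, LFPRecording, SpikeTrainSet
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "BANDS",
    "BandDecomposition",
    "CSDMap",
    "wavelet_band",
    "band_power_change",
    "detect_gamma_epochs",
    "compute_csd",
    "spectrogram_gamma_peaks",
    "gamma_peak_shuffle_test",
    "score_wake",
    "select_reference_channel",
]

BANDS = {"theta": (4.0, 12.0), "beta": (12.0, 30.0), "gamma": (30.0, 80.0)}
MORLET_W0 = 6.0
GRID_DT = 0.004  # s
N_FREQS = 8


@dataclass
class BandDecomposition:
    band: str
    freq_range: tuple
    times: np.ndarray  # 4 ms grid, seconds
    phase: np.ndarray  # radians in (-pi, pi], from the max-power frequency bin
    amplitude: np.ndarray  # a.u., unit-amplitude sinusoid at a center freq -> ~1
    dominant_freq: np.ndarray  # Hz
    center_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def grid_fs(self) -> float:
        return 1.0 / GRID_DT


@dataclass
class CSDMap:
    """Second spatial difference of event-aligned LFP.

    Sign convention: positive values mark current sinks (the extracellular
    potential has a local minimum in depth at a sink, making its second
    spatial difference positive).
    """

    values: np.ndarray  # (n_channels - 2, n_lags)
    channels: np.ndarray  # interior channel indices
    lags: np.ndarray  # seconds relative to alignment
    n_alignments: int
    sign_convention: str = "positive=sink"


def _morlet_kernel(freq: float, fs: float) -> np.ndarray:
    """Complex Morlet at `freq`, scaled so a unit-amplitude sinusoid at the
    center frequency yields |W| ~ 1."""
    sigma_t = MORLET_W0 / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-0.5 * (t / sigma_t) ** 2)
    kern = env * np.exp(2j * np.pi * freq * t)
    return kern / (0.5 * env.sum())


def wavelet_band(
    lfp_channel: np.ndarray,
    fs: float,
    band: str,
    n_freqs: int = N_FREQS,
) -> BandDecomposition:
    """Decompose one LFP channel within a named band (theta/beta/gamma)."""
    if band not in BANDS:
        raise InvalidParameterError(f"unknown band {band!r}; pick from {list(BANDS)}")
    f_lo, f_hi = BANDS[band]
    if fs < 2.0 * f_hi:
        raise InvalidParameterError(
            f"fs={fs} Hz below Nyquist for band upper edge {f_hi} Hz"
        )
    x = np.asarray(lfp_channel, dtype=float)
    freqs = np.geomspace(f_lo, f_hi, n_freqs)
    step = max(int(round(GRID_DT * fs)), 1)
    grid = np.arange(0, x.size, step)

    W = np.empty((n_freqs, grid.size), dtype=complex)
    for i, f in enumerate(freqs):
        conv = sps.fftconvolve(x, _morlet_kernel(f, fs), mode="same")
        W[i] = conv[grid]

    power = np.abs(W) ** 2
    best = np.argmax(power, axis=0)
    cols = np.arange(grid.size)
    return BandDecomposition(
        band=band,
        freq_range=(f_lo, f_hi),
        times=grid / fs,
        phase=np.angle(W[best, cols]),
        amplitude=np.abs(W[best, cols]),
        dominant_freq=freqs[best],
        center_freqs=freqs,
    )


def band_power_change(
    pre: BandDecomposition, post: BandDecomposition
) -> float:
    """Change in mean band amplitude, post vs pre, in dB (20 log10 ratio)."""
    a_pre = float(np.mean(pre.amplitude))
    a_post = float(np.mean(post.amplitude))
    if a_pre <= 0:
        raise InvalidInputError("zero pre-segment amplitude: ratio undefined")
    return 20.0 * np.log10(a_post / a_pre)


def detect_gamma_epochs(
    decomp: BandDecomposition,
    threshold_sd: float = 2.0,
    smooth_window: float = 0.050,
) -> tuple[EventIntervalSet, np.ndarray]:
    """Epochs where smoothed band power exceeds mean + threshold_sd * SD,
    each paired with the oscillation trough time nearest its center.

    Power is the squared wavelet amplitude smoothed with a
    ``smooth_window`` moving average (~2 gamma cycles by default). Troughs
    are the grid points where the instantaneous phase wraps through pi.
    Returns (epochs, trough_times).
    """
    power = decomp.amplitude**2
    w = max(int(round(smooth_window / GRID_DT)), 1)
    sm = np.convolve(power, np.ones(w) / w, mode="same")
    sd = sm.std()
    if sd == 0:
        warnings.warn("constant power signal: no epochs detectable", stacklevel=2)
        return EventIntervalSet(np.empty((0, 2)), label="gamma_epoch"), np.empty(0)
    thresh = sm.mean() + threshold_sd * sd
    above = sm > thresh
    if not above.any():
        return EventIntervalSet(np.empty((0, 2)), label="gamma_epoch"), np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]

    # phase wrap (+pi -> -pi) marks the oscillation trough
    wraps = np.flatnonzero(np.diff(decomp.phase) < -np.pi)
    troughs = []
    intervals = []
    for s, e in zip(starts, stops):
        center = (s + e) / 2.0
        intervals.append([decomp.times[s], decomp.times[min(e, decomp.times.size - 1)]])
        cand = wraps[(wraps >= max(s - w, 0)) & (wraps < min(e + w, decomp.phase.size))]
        if cand.size:
            troughs.append(decomp.times[cand[np.argmin(np.abs(cand - center))]])
        else:
            troughs.append(decomp.times[int(center)])
    epochs = EventIntervalSet(
        intervals, label="gamma_epoch",
        params=dict(threshold_sd=threshold_sd, smooth_window=smooth_window),
    )
    return epochs, np.asarray(troughs)


def compute_csd(
    lfp: LFPRecording,
    align_times: np.ndarray,
    half_window: float = 0.050,
) -> CSDMap:
    """Average the LFP around ``align_times`` and take the second spatial
    difference across the (depth-ordered) channels.

    ``CSD(ch, t) = V(ch-1, t) - 2 V(ch, t) + V(ch+1, t)`` on the aligned
    average, for interior channels; positive = sink.
    """
    if lfp.n_channels < 3:
        raise InvalidInputError("CSD needs at least 3 channels")
    align_times = np.asarray(align_times, dtype=float)
    if align_times.size == 0:
        raise InvalidInputError("no alignment times")
    half = int(round(half_window * lfp.fs))
    lags = np.arange(-half, half + 1) / lfp.fs
    acc = np.zeros((lfp.n_channels, lags.size))
    used = 0
    for t in align_times:
        i = int(round(t * lfp.fs))
        if i - half < 0 or i + half + 1 > lfp.n_samples:
            continue
        acc += lfp.samples[:, i - half : i + half + 1]
        used += 1
    if used == 0:
        raise InvalidInputError("all alignment times too close to the edges")
    avg = acc / used
    csd = avg[:-2] - 2.0 * avg[1:-1] + avg[2:]
    return CSDMap(
        values=csd,
        channels=np.arange(1, lfp.n_channels - 1),
        lags=lags,
        n_alignments=used,
    )


def spectrogram_gamma_peaks(
    segments: list,
    fs: float = 1250.0,
    nperseg: int = 1024,
    noverlap: int = 512,
    band: tuple = (30.0, 80.0),
) -> np.ndarray:
    """Per-segment peak gamma power (dB): the maximum of the Hamming
    spectrogram within 30-80 Hz over each (>= nperseg-sample) segment."""
    peaks = []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.size < nperseg:
            raise InvalidInputError(
                f"segment of {seg.size} samples shorter than the {nperseg} window"
            )
        f, t, S = sps.spectrogram(
            seg, fs=fs, window=sps.get_window("hamming", nperseg), noverlap=noverlap
        )
        sel = (f >= band[0]) & (f <= band[1])
        peaks.append(10.0 * np.log10(S[sel].max()))
    return np.asarray(peaks)


def gamma_peak_shuffle_test(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Group difference in mean peak gamma power with a label-shuffle null.

    Returns (mean_b - mean_a in dB, two-sided p = (1 + #{|null| >= |obs|})
    / (1 + n_shuffles)).
    """
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 segments per group to permute")
    obs = b.mean() - a.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(pooled)
        null[s] = perm[a.size :].mean() - perm[: a.size].mean()
    p = (1.0 + np.sum(np.abs(null) >= np.abs(obs))) / (1.0 + n_shuffles)
    return float(obs), float(p)


def score_wake(
    lfp_channel: np.ndarray,
    fs: float,
    movement: np.ndarray = None,
    movement_fs: float = None,
    ratio_threshold: float = 2.0,
    window: float = 2.0,
    step: float = 1.0,
    min_state: float = 10.0,
) -> EventIntervalSet:
    """Automatic wake segmentation from the theta/delta power ratio.

    A window is wake when theta (5-11 Hz) / delta (1-4 Hz) Welch power
    exceeds ``ratio_threshold`` OR the movement signal exceeds its own
    mean + 2 SD; states shorter than ``min_state`` are absorbed into the
    preceding state. Without a movement signal a warning is issued and the
    ratio alone decides.
    """
    x = np.asarray(lfp_channel, dtype=float)
    if movement is None:
        warnings.warn("no movement signal: wake scored on theta/delta ratio only",
                      stacklevel=2)
    nwin = int(round(window * fs))
    nstep = int(round(step * fs))
    starts = np.arange(0, x.size - nwin + 1, nstep)
    if starts.size == 0:
        raise InvalidInputError("signal shorter than one scoring window")

    if movement is not None:
        movement = np.asarray(movement, dtype=float)
        mfs = movement_fs if movement_fs is not None else fs
        mthr = movement.mean() + 2.0 * movement.std()

    wake = np.zeros(starts.size, dtype=bool)
    for k, s in enumerate(starts):
        seg = x[s : s + nwin]
        f, p = sps.welch(seg, fs=fs, nperseg=min(nwin, int(fs)))
        theta = p[(f >= 5) & (f <= 11)].sum()
        delta = p[(f >= 1) & (f <= 4)].sum()
        ratio = theta / delta if delta > 0 else np.inf
        w = ratio > ratio_threshold
        if movement is not None:
            m0 = int(s / fs * mfs)
            m1 = int((s + nwin) / fs * mfs)
            w = w or movement[m0:m1].max(initial=0.0) > mthr
        wake[k] = w

    # absorb runs shorter than min_state into their predecessor
    min_run = max(int(round(min_state / step)), 1)
    labels = wake.copy()
    i = 0
    while i < labels.size:
        j = i
        while j < labels.size and labels[j] == labels[i]:
            j += 1
        if j - i < min_run and i > 0:
            labels[i:j] = labels[i - 1]
        i = j

    intervals = []
    i = 0
    while i < labels.size:
        j = i
        while j < labels.size and labels[j] == labels[i]:
            j += 1
        if labels[i]:
            t0 = starts[i] / fs
            t1 = (starts[j - 1] + nwin) / fs if j - 1 < starts.size else x.size / fs
            intervals.append([t0, min(t1, x.size / fs)])
        i = j
    # merge touching wake intervals produced by the overlap
    merged = []
    for t0, t1 in intervals:
        if merged and t0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t1)
        else:
            merged.append([t0, t1])
    return EventIntervalSet(merged, label="wake",
                            params=dict(ratio_threshold=ratio_threshold,
                                        min_state=min_state))


def select_reference_channel(spikes: SpikeTrainSet, lfp: LFPRecording) -> int:
    """Channel with the most putative-excitatory unit waveforms; ties are
    broken by gamma-band wavelet amplitude."""
    counts = np.zeros(lfp.n_channels, dtype=int)
    for u in spikes:
        if u.label == "E" and u.peak_channel is not None:
            counts[u.peak_channel] += 1
    if counts.sum() == 0:
        raise InvalidInputError("no excitatory units with peak-channel assignments")
    best = np.flatnonzero(counts == counts.max())
    if best.size == 1:
        return int(best[0])
    gamma_amp = [
        float(np.mean(wavelet_band(lfp.samples[ch], lfp.fs, "gamma").amplitude))
        for ch in best
    ]
    return int(best[int(np.argmax(gamma_amp))])
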