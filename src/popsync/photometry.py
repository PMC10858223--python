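"""Fiber-photometry processing: dF/F, spontaneous calcium-event
detection, and odor-evoked response quantification.

Raw fluorescence is normalized to a sliding 50 s mean, smoothed with a
20 ms window, and high-pass filtered at 0.02 Hz; spontaneous events are
excursions above 3 SD lasting at least 50 ms, with a 200 ms refractory
between events.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "CalciumEvent",
    "compute_dff",
    "detect_calcium_events",
    "odor_evoked_dff",
]

BASELINE_WINDOW = 50.0  # s
SMOOTH_WINDOW = 0.02  # s
HIGHPASS_HZ = 0.02
THRESHOLD_SD = 3.0
MIN_WIDTH = 0.050  # s above threshold
REFRACTORY = 0.200  # s between events


@dataclass
class CalciumEvent:
    onset: float  # s
    peak_time: float  # s
    peak_dff_sd: float  # peak height in SD units of the analyzed trace
    duration: float  # s


def compute_dff(
    raw_f: np.ndarray,
    fs: float,
    baseline_window: float = BASELINE_WINDOW,
    smooth_window: float = SMOOTH_WINDOW,
    highpass: float = HIGHPASS_HZ,
) -> np.ndarray:
    """dF/F: (F - F50)/F50 with a centered sliding 50 s mean, then 20 ms
    moving-average smoothing, then a zero-phase first-order Butterworth
    high-pass at 0.02 Hz."""
    f = np.asarray(raw_f, dtype=float)
    if f.size < baseline_window * fs:
        raise InvalidInputError(
            f"trace shorter than the {baseline_window} s baseline window"
        )
    nb = int(round(baseline_window * fs))
    f0 = uniform_filter1d(f, size=nb, mode="nearest")
    if np.any(f0 <= 0):
        raise InvalidInputError("non-positive baseline mean: dF/F undefined")
    dff = (f - f0) / f0
    ns = max(int(round(smooth_window * fs)), 1)
    dff = uniform_filter1d(dff, size=ns, mode="nearest")
    if highpass > 0:
        sos = sps.butter(1, highpass, btype="highpass", fs=fs, output="sos")
        dff = sps.sosfiltfilt(sos, dff)
    return dff


def detect_calcium_events(
    dff: np.ndarray,
    fs: float,
    threshold_sd: float = THRESHOLD_SD,
    analysis_window: tuple = None,
    min_width: float = MIN_WIDTH,
    refractory: float = REFRACTORY,
) -> tuple[list[CalciumEvent], float]:
    """Threshold dF/F into calcium events; returns (events, rate events/s).

    The center and SD come from the analysis window (the full trace by
    default) and are estimated robustly (median and 1.4826 * MAD), so the
    transients being detected do not inflate the threshold they are
    compared against. An event is a supra-threshold run of at least
    ``min_width`` s, and runs starting within ``refractory`` s of the
    previous event's end are absorbed into it. Peak heights are reported
    in SD units, so every event satisfies peak >= ``threshold_sd``.
    """
    dff = np.asarray(dff, dtype=float)
    if analysis_window is not None:
        i0 = max(int(analysis_window[0] * fs), 0)
        i1 = min(int(analysis_window[1] * fs), dff.size)
        x = dff[i0:i1]
        t_off = i0 / fs
    else:
        x = dff
        t_off = 0.0
    if x.size < 60 * fs:
        warnings.warn("analysis window shorter than 60 s: SD estimate unstable",
                      stacklevel=2)
    mu = float(np.median(x))
    sd = 1.4826 * float(np.median(np.abs(x - mu)))
    if sd == 0:
        return [], 0.0
    thresh = mu + threshold_sd * sd
    above = x > thresh
    if not above.any():
        return [], 0.0
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, x.size]

    min_n = int(round(min_width * fs))
    runs = [(s, e) for s, e in zip(starts, stops) if e - s >= min_n]
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) / fs < refractory:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    events = []
    for s, e in merged:
        seg = x[s:e]
        ipk = s + int(np.argmax(seg))
        events.append(
            CalciumEvent(
                onset=t_off + s / fs,
                peak_time=t_off + ipk / fs,
                peak_dff_sd=float((x[ipk] - mu) / sd),
                duration=(e - s) / fs,
            )
        )
    rate = len(events) / (x.size / fs)
    return events, rate


def odor_evoked_dff(
    raw_f: np.ndarray,
    fs: float,
    odor_onsets: dict,
    response_start: float = 1.0,
    response_len: float = 4.0,
    baseline_len: float = 4.0,
    n_presentations: int = 3,
) -> dict:
    """Odor-evoked fluorescence response per odorant.

    For each presentation: mean raw F over the 4 s window starting 1 s
    after odor onset, normalized (dF/F) to the mean over the 4 s
    immediately before onset; the ``n_presentations`` consecutive values
    are averaged. ``odor_onsets`` maps odorant -> onset times (s).
    """
    f = np.asarray(raw_f, dtype=float)
    out = {}
    for od, onsets in odor_onsets.items():
        onsets = np.asarray(onsets, dtype=float)
        if onsets.size < n_presentations:
            raise InvalidParameterError(
                f"{od!r}: need {n_presentations} presentations, got {onsets.size}"
            )
        onsets = onsets[:n_presentations]
        # windows must not overlap across presentations
        spans = np.array(
            [[on - baseline_len, on + response_start + response_len] for on in onsets]
        )
        if np.any(spans[1:, 0] < spans[:-1, 1]):
            raise InvalidInputError(f"{od!r}: presentation windows overlap")
        vals = []
        for on in onsets:
            b0, b1 = int((on - baseline_len) * fs), int(on * fs)
            r0 = int((on + response_start) * fs)
            r1 = int((on + response_start + response_len) * fs)
            if b0 < 0 or r1 > f.size:
                raise InvalidInputError(f"{od!r}: window outside the trace")
            base = f[b0:b1].mean()
            if base <= 0:
                raise InvalidInputError("non-positive baseline fluorescence")
            vals.append((f[r0:r1].mean() - base) / base)
        out[od] = float(np.mean(vals))
    return out
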