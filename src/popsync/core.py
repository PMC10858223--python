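"""Core in-memory containers shared by every analysis stage.

All times are seconds (float64) on a single session clock starting at 0.
Every interval is half-open ``[start, stop)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "SpikeUnit",
    "SpikeTrainSet",
    "LFPRecording",
    "EventIntervalSet",
    "TrialTable",
    "RespirationTrace",
    "PhotometryTrace",
    "GroundTruth",
    "SyntheticSession",
]


@dataclass
class SpikeUnit:
    """One sorted unit: spike times plus optional waveform and label metadata.

    Parameters
    ----------
    unit_id
        Unique string identifier.
    spike_times
        Spike times in seconds, sorted ascending.
    waveform
        Mean spike waveform samples (a.u.), trough-dominated, or None.
    waveform_fs
        Sampling rate of ``waveform`` in Hz.
    features
        ``(trough_to_peak_ms, spike_width_ms)`` or None.
    label
        One of ``{"E", "I", "ambiguous", "unclassified"}``.
    label_confidence
        Posterior probability of the assigned mixture component.
    peak_channel
        Index of the channel carrying the largest waveform, if known.
    """

    unit_id: str
    spike_times: np.ndarray
    waveform: Optional[np.ndarray] = None
    waveform_fs: Optional[float] = None
    features: Optional[tuple] = None
    label: str = "unclassified"
    label_confidence: float = float("nan")
    peak_channel: Optional[int] = None

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise InvalidInputError("spike_times must be 1-D")
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise InvalidInputError(
                f"unit {self.unit_id}: spike times not sorted ascending"
            )
        if self.label not in ("E", "I", "ambiguous", "unclassified"):
            raise InvalidInputError(f"unknown label {self.label!r}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration: float) -> float:
        """Mean firing rate over ``duration`` seconds."""
        return self.n_spikes / duration


class SpikeTrainSet:
    """Ordered collection of :class:`SpikeUnit` with unique ids."""

    def __init__(self, units: Sequence[SpikeUnit]):
        ids = [u.unit_id for u in units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate unit_id(s): {dupes}")
        self._units = list(units)
        self._by_id = {u.unit_id: u for u in self._units}

    def __len__(self):
        return len(self._units)

    def __iter__(self):
        return iter(self._units)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self._by_id[key]
        return self._units[key]

    @property
    def unit_ids(self):
        return [u.unit_id for u in self._units]

    def select(self, label: str) -> "SpikeTrainSet":
        """Sub-collection of units carrying ``label``."""
        return SpikeTrainSet([u for u in self._units if u.label == label])

    def __repr__(self):
        return f"SpikeTrainSet(n_units={len(self)})"


@dataclass
class LFPRecording:
    """Multichannel LFP, channels ordered superficial to deep.

    ``samples`` is channel x time (a.u.), ``fs`` in Hz (pipeline default
    1250), ``channel_depths`` strictly monotonic in depth.
    """

    samples: np.ndarray
    fs: float
    channel_depths: np.ndarray
    channel_ids: Optional[list] = None
    volts_per_unit: float = 1.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")
        if self.channel_depths.size != self.samples.shape[0]:
            raise InvalidInputError("channel_depths length != n_channels")
        d = np.diff(self.channel_depths)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("channel depths must be strictly monotonic")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.samples.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


class EventIntervalSet:
    """Sorted, non-overlapping half-open intervals ``[start, stop)`` in seconds."""

    def __init__(self, intervals, label: str = "custom", params: Optional[dict] = None):
        iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise InvalidInputError("every interval needs stop > start")
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise InvalidInputError("intervals overlap")
        self.intervals = iv
        self.label = label
        self.params = dict(params or {})

    def __len__(self):
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def stops(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def contains(self, times) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside any interval ([start, stop))."""
        times = np.asarray(times, dtype=float)
        if not len(self):
            return np.zeros(times.shape, dtype=bool)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(times.shape, dtype=bool)
        inside[ok] = times[ok] < self.stops[idx[ok]]
        return inside

    def restrict(self, times) -> np.ndarray:
        """Subset of ``times`` inside the intervals."""
        times = np.asarray(times, dtype=float)
        return times[self.contains(times)]

    def __repr__(self):
        return (
            f"EventIntervalSet(label={self.label!r}, n={len(self)}, "
            f"total={self.total_duration:.3f}s)"
        )


class TrialTable:
    """Odor presentation schedule.

    Wraps a DataFrame with columns ``trial_id, odorant, concentration,
    onset, offset, is_control`` sorted by onset.
    """

    COLUMNS = ["trial_id", "odorant", "concentration", "onset", "offset", "is_control"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"trial table missing columns: {missing}")
        df = df[self.COLUMNS].sort_values("onset").reset_index(drop=True)
        if np.any(df["offset"].to_numpy() <= df["onset"].to_numpy()):
            raise InvalidInputError("every trial needs offset > onset")
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def odorants(self):
        """Odorant labels excluding the mineral-oil control, sorted."""
        return sorted(self.df.loc[~self.df["is_control"], "odorant"].unique())

    def trials_for(self, odorant: str) -> pd.DataFrame:
        return self.df[self.df["odorant"] == odorant]

    @property
    def control_trials(self) -> pd.DataFrame:
        return self.df[self.df["is_control"]]


@dataclass
class RespirationTrace:
    """Nasal-pressure signal; inhalation onsets are filled in by detection."""

    pressure: np.ndarray
    fs: float
    inhalation_onsets: Optional[np.ndarray] = None

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")
        if self.inhalation_onsets is not None:
            o = np.asarray(self.inhalation_onsets, dtype=float)
            if o.size and np.any(np.diff(o) < 0):
                raise InvalidInputError("inhalation onsets not sorted")
            self.inhalation_onsets = o

    @property
    def duration(self) -> float:
        return self.pressure.size / self.fs


@dataclass
class PhotometryTrace:
    """Raw fluorescence plus, once processed, the derived dF/F and events."""

    raw_f: np.ndarray
    fs: float
    dff: Optional[np.ndarray] = None
    events: Optional[np.ndarray] = None

    def __post_init__(self):
        self.raw_f = np.asarray(self.raw_f, dtype=float)
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.raw_f.size / self.fs


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic session, for parameter-recovery tests."""

    seed: int = 0
    popevent_intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    popevent_rate: float = 0.0
    unit_base_rates: dict = field(default_factory=dict)
    gamma_lock: dict = field(default_factory=dict)  # unit_id -> (mu, kappa)
    odor_effects: dict = field(default_factory=dict)  # (unit_id, odorant) -> gain
    pair_signal_corr_target: Optional[float] = None
    calcium_event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    calcium_event_amplitude: float = 0.0
    inhalation_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        iv = np.asarray(self.popevent_intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(np.diff(iv[:, 0]) < 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
                raise InvalidInputError("planted intervals must be sorted, non-overlapping")
        self.popevent_intervals = iv


@dataclass
class SyntheticSession:
    """Bundle of everything a synthetic session generated, plus its truth."""

    truth: GroundTruth
    duration: float
    spikes: Optional[SpikeTrainSet] = None
    lfp: Optional[LFPRecording] = None
    respiration: Optional[RespirationTrace] = None
    trials: Optional[TrialTable] = None
    photometry: Optional[PhotometryTrace] = None
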