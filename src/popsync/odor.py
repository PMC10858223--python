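"""Inhalation-aligned odor responses.

Spiking is aligned to the first inhalation after odor onset; evoked
rates are computed in the 350 ms post-inhalation window and baselines
from the first breath within the 2 s window that ends 1 s before odor
onset. Odor responsiveness is scored by cumulative Poisson surprise: per
10 ms bin, -ln of the Poisson tail probability of the summed observed
count given the trial-averaged baseline rate, summed over the 35-bin
window, with the mineral-oil control surprise subtracted; significance
thresholds come from trial-label shuffles pooled across unit-odorant
combinations at a 5% false discovery rate (> 95% of the shuffles).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import RespirationTrace, SpikeTrainSet, TrialTable
from .errors import InsufficientDataError, InvalidInputError
from .synth import CONTROL_ODORANT

__all__ = [
    "SurpriseResult",
    "detect_inhalation_onsets",
    "evoked_rates",
    "surprise_analysis",
    "session_surprise",
    "signal_correlation",
    "noise_correlation",
]

RESPONSE_WINDOW = 0.350  # s after the first inhalation in odor
SURPRISE_BIN = 0.010  # s
BASELINE_BEFORE = 3.0  # baseline window starts this long before odor onset
BASELINE_LEN = 2.0  # and lasts this long (ends 1 s before onset)
P_FLOOR = 1e-300
BASELINE_RATE_FLOOR = 0.1  # Hz, for the normalized-rate ratio


@dataclass
class SurpriseResult:
    unit_id: str
    odorant: str
    cumulative_surprise: float  # nats, oil-subtracted
    shuffle_distribution: np.ndarray
    threshold: float
    significant: bool
    direction: str  # activated | inhibited
    per_bin_surprise: np.ndarray = field(default_factory=lambda: np.empty(0))


def detect_inhalation_onsets(
    respiration: RespirationTrace,
    band: tuple = (0.5, 15.0),
    min_separation: float = 0.100,
) -> np.ndarray:
    """Inhalation onsets: negative-going zero crossings of the band-passed
    (0.5-15 Hz) pressure signal, at least 100 ms apart.

    A simplified breath detector standing in for full breath-waveform
    parameterization; on clean nasal-pressure records the negative-going
    crossing marks the start of inspiratory flow.
    """
    p = respiration.pressure
    fs = respiration.fs
    if p.size < 2 * fs:
        raise InvalidInputError("pressure trace shorter than 2 s")
    if np.ptp(p) == 0:
        warnings.warn("flat pressure trace: no breaths detected", stacklevel=2)
        return np.empty(0)
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, p)
    down = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0))
    # linear interpolation of the crossing instant
    frac = x[down] / (x[down] - x[down + 1])
    t = (down + frac) / fs
    kept = []
    last = -np.inf
    for ti in t:
        if ti - last >= min_separation:
            kept.append(ti)
            last = ti
    onsets = np.asarray(kept)
    respiration.inhalation_onsets = onsets
    return onsets


def _first_onset_in(onsets: np.ndarray, start: float, stop: float):
    i = np.searchsorted(onsets, start)
    if i < onsets.size and onsets[i] < stop:
        return float(onsets[i])
    return None


def _window_counts(spike_times, t0, window, bin):
    """Spike counts in consecutive `bin`-wide bins of [t0, t0+window)."""
    n = int(round(window / bin))
    edges = t0 + np.arange(n + 1) * bin
    c, _ = np.histogram(spike_times, bins=edges)
    return c


def evoked_rates(
    spike_times: np.ndarray,
    trials: TrialTable,
    onsets: np.ndarray,
    window: float = RESPONSE_WINDOW,
) -> pd.DataFrame:
    """Per-trial odor and baseline rates for one unit.

    odor_rate: spikes in [first inhalation >= odor onset, +350 ms) / 0.35.
    baseline_rate: same window after the first breath inside the 2 s
    baseline window (3 s to 1 s before odor onset). normalized_rate is
    their ratio with the baseline floored at 0.1 Hz. Trials without an
    odor inhalation are skipped.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    rows = []
    for row in trials.df.itertuples():
        t_in = _first_onset_in(onsets, row.onset, row.offset)
        if t_in is None:
            continue
        t_base = _first_onset_in(
            onsets, row.onset - BASELINE_BEFORE,
            row.onset - BASELINE_BEFORE + BASELINE_LEN,
        )
        if t_base is None:
            continue
        n_odor = np.count_nonzero(
            (spike_times >= t_in) & (spike_times < t_in + window)
        )
        n_base = np.count_nonzero(
            (spike_times >= t_base) & (spike_times < t_base + window)
        )
        odor_rate = n_odor / window
        base_rate = n_base / window
        rows.append(
            dict(
                trial_id=row.trial_id,
                odorant=row.odorant,
                is_control=row.is_control,
                odor_rate=odor_rate,
                baseline_rate=base_rate,
                normalized_rate=odor_rate / max(base_rate, BASELINE_RATE_FLOOR),
                t_inhale=t_in,
                t_baseline=t_base,
            )
        )
    return pd.DataFrame(rows)


def _counts_matrices(spike_times, trials_df, onsets, window, bin):
    """(odor_counts, base_counts): per-trial per-bin spike counts aligned to
    the first inhalation in odor and to the first baseline breath."""
    odor, base = [], []
    for row in trials_df.itertuples():
        t_in = _first_onset_in(onsets, row.onset, row.offset)
        t_base = _first_onset_in(
            onsets, row.onset - BASELINE_BEFORE,
            row.onset - BASELINE_BEFORE + BASELINE_LEN,
        )
        if t_in is None or t_base is None:
            continue
        odor.append(_window_counts(spike_times, t_in, window, bin))
        base.append(_window_counts(spike_times, t_base, window, bin))
    if not odor:
        return np.empty((0, 0)), np.empty((0, 0))
    return np.array(odor), np.array(base)


def _cumulative_surprise(odor_counts, base_counts):
    """(activation, inhibition, per-bin activation surprise).

    Per bin, the summed count across trials is tested against a Poisson
    whose mean is the summed baseline count (trial-averaged baseline rate
    x bin width x n_trials); surprise = -ln p with the survival function
    for activation and the CDF for inhibition, summed over bins.
    """
    k = odor_counts.sum(axis=0)
    lam = base_counts.sum(axis=0).astype(float)
    lam = np.maximum(lam, 1e-12)
    p_act = np.clip(stats.poisson.sf(k - 1, lam), P_FLOOR, 1.0)
    p_inh = np.clip(stats.poisson.cdf(k, lam), P_FLOOR, 1.0)
    s_act = -np.log(p_act)
    s_inh = -np.log(p_inh)
    return float(s_act.sum()), float(s_inh.sum()), s_act


def _shuffled_surprises(rng, odor_counts, base_counts, oil_odor, oil_base, n_shuffles):
    """Null statistics from permuting odor-vs-baseline window labels.

    Each shuffle re-assigns, per trial, which of the two count vectors is
    'odor' and which 'baseline' (a fair permutation of the 2n windows),
    recomputes both directed cumulative surprises with the identically
    shuffled mineral-oil term subtracted, and keeps max(act, inh) — the
    same statistic that is thresholded on the real labels.
    """
    def directed(odor_c, base_c, swaps):
        # (n_shuffles, n_bins) summed counts after per-trial label swaps
        k = swaps @ base_c + (1.0 - swaps) @ odor_c
        lam = np.maximum(swaps @ odor_c + (1.0 - swaps) @ base_c, 1e-12)
        s_act = -np.log(np.clip(stats.poisson.sf(k - 1, lam), P_FLOOR, 1.0))
        s_inh = -np.log(np.clip(stats.poisson.cdf(k, lam), P_FLOOR, 1.0))
        return s_act.sum(axis=1), s_inh.sum(axis=1)

    swaps = (rng.random((n_shuffles, odor_counts.shape[0])) < 0.5).astype(float)
    a, i = directed(odor_counts, base_counts, swaps)
    swaps_oil = (rng.random((n_shuffles, oil_odor.shape[0])) < 0.5).astype(float)
    oa, oi = directed(oil_odor, oil_base, swaps_oil)
    return np.maximum(a - oa, i - oi)


def surprise_analysis(
    spike_times: np.ndarray,
    trials: TrialTable,
    onsets: np.ndarray,
    unit_id: str = "",
    n_shuffles: int = 100,
    bin: float = SURPRISE_BIN,
    window: float = RESPONSE_WINDOW,
    fdr: float = 0.05,
    min_trials: int = 5,
    seed: int = 0,
) -> list[SurpriseResult]:
    """Cumulative-surprise responsiveness of one unit to every odorant.

    The threshold is the (1 - fdr) quantile of the shuffle statistics
    pooled across this unit's odorants; to pool across a whole session
    (the recommended null, mirroring one pooled distribution for all
    unit-odor combinations) use :func:`session_surprise`.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    oil = trials.control_trials
    if len(oil) < min_trials:
        raise InsufficientDataError("need mineral-oil control trials")
    oil_odor, oil_base = _counts_matrices(spike_times, oil, onsets, window, bin)
    if oil_odor.size == 0:
        raise InsufficientDataError("no usable control trials (missing breaths)")

    rng = np.random.default_rng(seed)
    oa, oi, _ = _cumulative_surprise(oil_odor, oil_base)

    partial = []
    pooled = []
    for od in trials.odorants:
        tdf = trials.trials_for(od)
        if len(tdf) < min_trials:
            raise InsufficientDataError(f"fewer than {min_trials} trials for {od!r}")
        oc, bc = _counts_matrices(spike_times, tdf, onsets, window, bin)
        if oc.size == 0:
            raise InsufficientDataError(f"no usable trials for {od!r}")
        a, i, s_bins = _cumulative_surprise(oc, bc)
        s_act, s_inh = a - oa, i - oi
        stat = max(s_act, s_inh)
        direction = "activated" if s_act >= s_inh else "inhibited"
        null = _shuffled_surprises(rng, oc, bc, oil_odor, oil_base, n_shuffles)
        pooled.append(null)
        partial.append((od, stat, direction, s_bins, null))

    pooled_null = np.concatenate(pooled)
    threshold = float(np.quantile(pooled_null, 1.0 - fdr))
    results = []
    for od, stat, direction, s_bins, null in partial:
        results.append(
            SurpriseResult(
                unit_id=unit_id,
                odorant=od,
                cumulative_surprise=stat,
                shuffle_distribution=null,
                threshold=threshold,
                significant=bool(stat > threshold),
                direction=direction,
                per_bin_surprise=s_bins,
            )
        )
    return results


def session_surprise(
    spikes: SpikeTrainSet,
    trials: TrialTable,
    onsets: np.ndarray,
    n_shuffles: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Surprise analysis for every unit with one pooled shuffle null.

    All unit-odorant shuffle statistics form a single pooled null
    distribution whose (1 - fdr) quantile is the common significance
    threshold.
    """
    per_unit = []
    for k, u in enumerate(spikes):
        res = surprise_analysis(
            u.spike_times, trials, onsets, unit_id=u.unit_id,
            n_shuffles=n_shuffles, fdr=fdr, seed=seed + k, **kwargs,
        )
        per_unit.extend(res)
    pooled = np.concatenate([r.shuffle_distribution for r in per_unit])
    threshold = float(np.quantile(pooled, 1.0 - fdr))
    rows = [
        dict(
            unit_id=r.unit_id,
            odorant=r.odorant,
            cumulative_surprise=r.cumulative_surprise,
            threshold=threshold,
            significant=r.cumulative_surprise > threshold,
            direction=r.direction,
        )
        for r in per_unit
    ]
    return pd.DataFrame(rows)


def signal_correlation(tuning_a: np.ndarray, tuning_b: np.ndarray) -> float:
    """Pearson correlation of two units' trial-averaged tuning vectors."""
    a = np.asarray(tuning_a, dtype=float)
    b = np.asarray(tuning_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise InvalidInputError("tuning vectors must match and have length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise InsufficientDataError("zero-variance tuning vector: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def noise_correlation(resp_a: np.ndarray, resp_b: np.ndarray) -> float:
    """Mean across trials of the per-trial Pearson correlation between the
    two units' residual responses (trial response minus the trial-averaged
    response), computed across time bins within each trial."""
    a = np.asarray(resp_a, dtype=float)
    b = np.asarray(resp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidInputError("need matching (n_trials, n_bins) matrices")
    if a.shape[0] < 2:
        raise InsufficientDataError("noise correlation needs >= 2 trials")
    ra = a - a.mean(axis=0, keepdims=True)
    rb = b - b.mean(axis=0, keepdims=True)
    rs = []
    for t in range(a.shape[0]):
        if ra[t].std() == 0 or rb[t].std() == 0:
            continue
        rs.append(np.corrcoef(ra[t], rb[t])[0, 1])
    if not rs:
        raise InsufficientDataError("all residuals degenerate")
    return float(np.mean(rs))
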