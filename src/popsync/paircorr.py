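"""Pairwise cross-correlograms, peak integrals, and ISI distributions.

CCGs use 10 ms bins over +-1 s of lag (201 bins) and are normalized by
the asymptotic mean rates of both units, so an independent stationary
pair sits at 1 in every bin.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventIntervalSet
from .errors import InsufficientDataError, InvalidParameterError

__all__ = ["CCGResult", "compute_ccg", "ccg_peak_integral", "isi_distribution"]

BIN_S = 0.010
HALF_WINDOW_S = 1.0
N_BINS = 201  # centered 10 ms bins spanning +-1000 ms


@dataclass
class CCGResult:
    lags: np.ndarray  # bin centers, seconds
    values: np.ndarray  # normalized correlation per bin
    n_ref: int
    n_target: int
    normalization: dict = field(default_factory=dict)


def _lag_edges() -> np.ndarray:
    # 201 bins centered on multiples of 10 ms: edges at -1.005 .. +1.005
    return (np.arange(N_BINS + 1) - N_BINS / 2.0) * BIN_S


def compute_ccg(
    ref: np.ndarray,
    target: np.ndarray,
    epochs: EventIntervalSet,
) -> CCGResult:
    """Rate-normalized cross-correlogram of ``target`` around ``ref`` spikes.

    For each 10 ms lag bin tau the raw count of target spikes at lag tau
    from every reference spike is divided by (opportunity x target mean
    rate x bin width), where opportunity counts the reference spikes for
    which that lag bin lies inside the epochs — reference spikes near an
    epoch edge only contribute the lags they could realize, which removes
    edge bias in short epochs.
    """
    ref = epochs.restrict(np.asarray(ref, dtype=float))
    target = epochs.restrict(np.asarray(target, dtype=float))
    if ref.size == 0 or target.size == 0:
        raise InsufficientDataError("empty spike train within epochs")
    total = epochs.total_duration
    rate_target = target.size / total

    edges = _lag_edges()
    counts = np.zeros(N_BINS)
    # histogram target-ref lags: for sorted trains use searchsorted windows
    lo = np.searchsorted(target, ref + edges[0])
    hi = np.searchsorted(target, ref + edges[-1])
    for r, a, b in zip(ref, lo, hi):
        if b > a:
            c, _ = np.histogram(target[a:b] - r, bins=edges)
            counts += c

    # per-bin opportunity: number of ref spikes whose lag bin center falls
    # inside the epochs
    centers = (edges[:-1] + edges[1:]) / 2.0
    opportunity = np.zeros(N_BINS)
    for j, c in enumerate(centers):
        opportunity[j] = epochs.contains(ref + c).sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        values = counts / (opportunity * rate_target * BIN_S)
    values[opportunity == 0] = np.nan

    return CCGResult(
        lags=centers,
        values=values,
        n_ref=int(ref.size),
        n_target=int(target.size),
        normalization=dict(
            rate_target_hz=rate_target, bin_s=BIN_S, total_epoch_s=total
        ),
    )


def ccg_peak_integral(
    ccg: CCGResult,
    lag_range: tuple = (-0.050, 0.050),
    baseline_band: tuple = (0.800, 1.000),
) -> float:
    """Baseline-subtracted integral of the CCG over ``lag_range`` (seconds).

    Baseline is the mean bin value at |lag| within ``baseline_band``; the
    excess above it is summed over the closed lag range and multiplied by
    the bin width, giving seconds of excess coincidence per reference
    spike per unit target rate.
    """
    lo, hi = lag_range
    tol = 1e-9
    if lo < ccg.lags[0] - BIN_S / 2 or hi > ccg.lags[-1] + BIN_S / 2:
        raise InvalidParameterError("lag_range outside +-1 s")
    # bin-aligned: each bound must sit on a bin center or edge
    for bound in (lo, hi):
        if min(abs(bound / BIN_S - round(bound / BIN_S)),
               abs(bound / BIN_S - 0.5 - round(bound / BIN_S - 0.5))) > tol:
            raise InvalidParameterError(f"lag bound {bound} not aligned to 10 ms bins")
    in_range = (ccg.lags >= lo - tol) & (ccg.lags <= hi + tol)
    in_base = (np.abs(ccg.lags) >= baseline_band[0] - tol) & (
        np.abs(ccg.lags) <= baseline_band[1] + tol
    )
    baseline = np.nanmean(ccg.values[in_base])
    return float(np.nansum(ccg.values[in_range] - baseline) * BIN_S)


def isi_distribution(
    spike_times: np.ndarray,
    window: float = 1.0,
    bin: float = 0.001,
) -> np.ndarray:
    """Normalized inter-spike-interval histogram: 1 ms bins over [0, 1 s),
    ISIs beyond the window dropped before normalizing to unit sum."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need >= 2 spikes for an ISI distribution")
    isi = np.diff(t)
    isi = isi[isi < window]
    if isi.size == 0:
        raise InsufficientDataError("no ISI within the 1 s window")
    n_bins = int(round(window / bin))
    hist, _ = np.histogram(isi, bins=n_bins, range=(0.0, window))
    return hist / hist.sum()
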