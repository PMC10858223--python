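"""Putative excitatory / inhibitory unit classification.

Units are separated with a 2-component Gaussian mixture on two waveform
features — trough-to-peak latency and spike width (trough full width at
half depth) — keeping only assignments whose posterior leaves at most
0.01 for the other component; the rest are labeled ambiguous. A
cross-correlogram jitter-surrogate screen for monosynaptic connections
provides an independent confirmation route, and a strict minimum-rate
filter (> 0.5 Hz) gates the downstream pairwise analyses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.mixture import GaussianMixture

from .core import EventIntervalSet, SpikeTrainSet
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "UnitLabelResult",
    "MonosynapticHit",
    "extract_waveform_features",
    "classify_units",
    "screen_monosynaptic",
    "filter_min_rate",
]

CONFIDENCE_P = 0.01  # max posterior mass allowed on the non-assigned component
MIN_SPIKES_MONO = 200


@dataclass
class UnitLabelResult:
    unit_id: str
    label: str  # E, I, or ambiguous
    posterior: float
    features: tuple


@dataclass
class MonosynapticHit:
    ref_unit: str
    target_unit: str
    sign: str  # excitatory | inhibitory
    lag_ms: float
    excess: float  # observed minus surrogate-mean count at the flagged lag


def extract_waveform_features(waveform: np.ndarray, fs: float) -> tuple[float, float]:
    """(trough_to_peak_ms, spike_width_ms) from a mean waveform.

    trough_to_peak: time from the global trough to the subsequent maximum.
    spike_width: full width of the trough at half its depth (measured from
    the pre-trough baseline), with linear interpolation at the crossings.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 5 or np.allclose(w, w[0]):
        raise InvalidInputError("waveform flat or too short to carry a trough")
    i_trough = int(np.argmin(w))
    if i_trough == 0 or i_trough == w.size - 1:
        raise InvalidInputError("no interior trough in waveform")
    i_peak = i_trough + int(np.argmax(w[i_trough:]))
    if i_peak == i_trough:
        raise InvalidInputError("no post-trough peak")
    trough_to_peak = (i_peak - i_trough) / fs * 1000.0

    base = np.median(w[: max(i_trough // 2, 1)])
    depth = base - w[i_trough]
    if depth <= 0:
        raise InvalidInputError("trough not below baseline")
    half = base - 0.5 * depth

    # walk out from the trough to the half-depth crossings, interpolating
    left = i_trough
    while left > 0 and w[left] < half:
        left -= 1
    right = i_trough
    while right < w.size - 1 and w[right] < half:
        right += 1
    xl = left + (half - w[left]) / (w[left + 1] - w[left]) if w[left] >= half else left
    xr = (
        right - (half - w[right]) / (w[right - 1] - w[right])
        if w[right] >= half
        else right
    )
    width = (xr - xl) / fs * 1000.0
    if width <= 0:
        raise InvalidInputError("degenerate trough width")
    return float(trough_to_peak), float(width)


def classify_units(
    features: dict,
    confidence_p: float = CONFIDENCE_P,
    seed: int = 0,
) -> list[UnitLabelResult]:
    """Fit a 2-component full-covariance Gaussian mixture on
    (trough_to_peak, spike_width) and label each unit E or I.

    The component with the larger mean trough-to-peak is excitatory. A
    unit is assigned its MAP component only if the posterior of the other
    component is <= ``confidence_p``; otherwise it is ambiguous. The fit
    is initialized by k-means on standardized features with 10 restarts
    and a fixed seed, so unit order never affects the labels.
    """
    ids = sorted(features)
    if len(ids) < 2:
        raise InsufficientDataError("need >= 2 units to fit a mixture")
    X = np.array([features[i] for i in ids], dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite waveform features")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=10,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-6,
    )
    try:
        gmm.fit(Z)
    except ValueError as exc:  # degenerate covariance etc.
        raise InvalidInputError(f"mixture fit failed: {exc}") from exc

    means_ttp = gmm.means_[:, 0] * sd[0] + mu[0]
    e_comp = int(np.argmax(means_ttp))
    post = gmm.predict_proba(Z)
    results = []
    for k, uid in enumerate(ids):
        p_e = post[k, e_comp]
        map_comp = int(p_e < 0.5)  # 0 -> E side
        p_assigned = max(p_e, 1.0 - p_e)
        if 1.0 - p_assigned <= confidence_p:
            label = "E" if p_e >= 0.5 else "I"
        else:
            label = "ambiguous"
        results.append(
            UnitLabelResult(
                unit_id=uid,
                label=label,
                posterior=float(p_assigned),
                features=tuple(X[k]),
            )
        )
    return results


def screen_monosynaptic(
    ref: np.ndarray,
    target: np.ndarray,
    jitter_window: float = 0.005,
    n_surrogates: int = 500,
    alpha: float = 0.01,
    bin: float = 0.001,
    lag_band: tuple = (0.001, 0.004),
    max_lag: float = 0.010,
    seed: int = 0,
    ref_unit: str = "ref",
    target_unit: str = "target",
) -> Optional[MonosynapticHit]:
    """Screen one ordered pair for a putative monosynaptic connection.

    Counts target spikes in 1 ms lag bins after each reference spike and
    compares the 1-4 ms band against a null built from ``n_surrogates``
    spike-jitter surrogates (target spikes jittered uniformly within
    +-``jitter_window``). A bin whose observed count exceeds the pointwise
    (1 - alpha/k) surrogate quantile (k = bins in the band, Bonferroni) is
    an excitatory hit; below the alpha/k quantile, inhibitory. Returns
    None when no bin is flagged.
    """
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    if ref.size < MIN_SPIKES_MONO or target.size < MIN_SPIKES_MONO:
        raise InsufficientDataError(
            f"need >= {MIN_SPIKES_MONO} spikes in both trains"
        )
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, max_lag + bin / 2, bin)

    def band_counts(tgt):
        tgt = np.sort(tgt)
        counts = np.zeros(edges.size - 1)
        lo = np.searchsorted(tgt, ref)
        hi = np.searchsorted(tgt, ref + max_lag)
        for r, a, b in zip(ref, lo, hi):
            if b > a:
                c, _ = np.histogram(tgt[a:b] - r, bins=edges)
                counts += c
        return counts

    obs = band_counts(target)
    null = np.empty((n_surrogates, edges.size - 1))
    for s in range(n_surrogates):
        jit = target + rng.uniform(-jitter_window, jitter_window, size=target.size)
        null[s] = band_counts(jit)

    centers = (edges[:-1] + edges[1:]) / 2.0
    in_band = (centers >= lag_band[0]) & (centers <= lag_band[1])
    k = int(in_band.sum())
    alpha_bin = alpha / k
    hi_q = np.quantile(null[:, in_band], 1.0 - alpha_bin, axis=0)
    lo_q = np.quantile(null[:, in_band], alpha_bin, axis=0)
    band_obs = obs[in_band]
    band_centers = centers[in_band]
    exc = band_obs > hi_q
    inh = band_obs < lo_q
    null_mean = null[:, in_band].mean(axis=0)
    if exc.any():
        j = int(np.argmax(band_obs - null_mean))
        return MonosynapticHit(
            ref_unit, target_unit, "excitatory",
            lag_ms=float(band_centers[j] * 1000.0),
            excess=float(band_obs[j] - null_mean[j]),
        )
    if inh.any():
        j = int(np.argmin(band_obs - null_mean))
        return MonosynapticHit(
            ref_unit, target_unit, "inhibitory",
            lag_ms=float(band_centers[j] * 1000.0),
            excess=float(band_obs[j] - null_mean[j]),
        )
    return None


def filter_min_rate(
    units: SpikeTrainSet,
    epochs: EventIntervalSet,
    min_rate: float = 0.5,
) -> SpikeTrainSet:
    """Keep units whose rate inside the epochs is strictly above ``min_rate``."""
    total = epochs.total_duration
    if total <= 0:
        raise InvalidInputError("zero total epoch duration")
    kept = []
    for u in units:
        n = int(epochs.contains(u.spike_times).sum())
        if min_rate == 0:
            if n >= 1:
                kept.append(u)
        elif n / total > min_rate:
            kept.append(u)
    return SpikeTrainSet(kept)
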