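# Methods

This note documents the models, parameters, and numerical choices
behind each analysis stage, what the synthetic generators do and do not
emulate, and the design decisions taken where a convention was
genuinely open. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` compute.

## Conventions

All times are seconds (float64) on a session clock starting at 0.
Every interval — population events, gamma epochs, wake states, trials —
is half-open `[start, stop)`: a spike exactly at `stop` is outside.
Every stochastic routine takes an integer seed and drives a
`numpy.random.default_rng`; identical parameters and seed reproduce
byte-identical outputs.

## Unit classification (`unitclass`)

Two waveform features: *trough-to-peak* (global trough to subsequent
maximum, ms) and *spike width*, defined here as the trough's full width
at half depth relative to the pre-trough baseline, with linear
interpolation at the crossings. FWHM was chosen because it is the
common convention and is invariant to amplitude scaling; the
alternative (inverse peak frequency of the spike spectrum) exists in
the literature but is less direct.

A 2-component full-covariance Gaussian mixture is fitted on the
standardized feature pairs (k-means init, 10 restarts, fixed seed, best
likelihood kept — so unit order never changes a label). The component
with the larger mean trough-to-peak is excitatory. The confidence gate
interprets "classification confidence P ≤ 0.01" as: the posterior mass
of the non-assigned component must be ≤ 0.01, otherwise the unit is
*ambiguous*. Fewer than 2 units is an error, as is any non-finite
feature.

The monosynaptic screen counts target spikes in 1 ms bins at 1–10 ms
lag after reference spikes and compares the 1–4 ms band against 500
spike-jitter surrogates (target spikes jittered uniformly in ±5 ms),
with a pointwise band at α Bonferroni-corrected over the band's bins.
Excess → excitatory hit, deficit → inhibitory. Fewer than 200 spikes in
either train raises an insufficient-data error rather than returning
"no hit", because absence of evidence at that count is not evidence of
absence. The jitter null destroys millisecond synchrony while
preserving slow co-modulation, which is exactly the confound to remove.

The rate filter is strict (`> 0.5 Hz` within the analysis epochs): a
unit at exactly 0.5 Hz is dropped.

## Population events (`popevents`)

Pooled excitatory spikes are binned at 1 ms and convolved with a
truncated Gaussian kernel: total support 60 ms (±30 ms), SD 10 ms,
renormalized to unit area — the only reading under which both printed
numbers are simultaneously meaningful. The smoothed series integrates
to the spike count, so its time average is the pooled mean rate.

Detection is two-threshold. The baseline mean μ and SD σ are computed
on the smoothed series restricted to the wake baseline epochs (events
included — they are part of the analyzed wake time). An event must
contain a peak ≥ μ + 3σ; its boundaries are the crossings of a lower
threshold μ + 0.5σ. Candidates separated by ≤ 50 ms are merged (merging
rather than deleting preserves the plain reading of the gap criterion
and is monotone in the threshold), then only durations within
[50, 500] ms survive. The constraints are asserted on every run.

Why not boundaries at the 3σ threshold itself? At a realistic regime
(12 units × 2 Hz, gain 5, 150 ms events) the smoothed rate inside an
event fluctuates around the threshold, so single events fragment into
sub-50 ms crossings and the duration filter silently discards roughly
half of them. The two-threshold construction (peak criterion + lower
boundary threshold) is the standard for burst and ripple detectors. The
boundary level of 0.5σ was fixed once by calibrating miss/false-event
balance on Poisson ground truth; it is a parameter
(`PopEventParams.boundary_sd`) and can be set to 3.0 to recover the
single-threshold behaviour. Note that threshold crossings on a Poisson
raster also produce occasional chance events; the detector makes no
attempt to distinguish those from planted ones.

`popevent_stats` reports events/s, % of epoch time inside events, and %
of excitatory spikes inside events. `exclude_event_spikes` removes
spikes with the half-open convention.

## Cross-correlograms and ISIs (`paircorr`)

201 centered 10 ms bins spanning ±1 s. For each lag bin τ, the count of
target spikes at lag τ from reference spikes is divided by
`opportunity(τ) × r_target × Δ`, where opportunity counts reference
spikes whose τ-shifted bin lies inside the epochs. For long epochs this
equals the classical `n_ref × r_target × Δ` normalization
(independence ⇒ 1, pair-symmetric up to lag negation); near epoch edges
it removes the bias short epochs would otherwise introduce. Bins with
zero opportunity are NaN.

The peak integral subtracts a flat baseline estimated from
|τ| ∈ [800, 1000] ms (the outer band used as the reference range in the
source analyses), sums the excess over the closed query range, and
multiplies by the bin width in seconds. Whether the original quantity
multiplied by bin width is unknown; it is a pure scale factor for any
comparison, and the seconds convention is recorded here.

ISI distributions: intervals > 1 s are dropped, the remainder histogram
into 1000 × 1 ms bins normalized to unit sum. Fewer than 2 spikes, or
no interval ≤ 1 s, is an insufficient-data error.

## LFP analysis (`lfp`)

**Wavelets.** Complex Morlet with ω₀ = 6 (the field default for phase
estimation; the original family is unstated) at 8 log-spaced center
frequencies per band — log spacing balances relative bandwidth across
the octave-plus gamma band. Kernels are scaled so a unit-amplitude
sinusoid at a center frequency yields |W| ≈ 1, making amplitudes
commensurate across frequencies. Per 4 ms grid point, phase, amplitude
and dominant frequency are taken from the frequency bin with maximal
power at that instant.

**Band power change** is `20·log10(mean amplitude post / pre)` in dB on
the wavelet amplitude (chosen over the filtered-signal envelope; the
two differ only in ripple).

**Gamma epochs.** Squared amplitude smoothed with a 50 ms moving
average (~2 gamma cycles; unstated in the source), thresholded at
mean + 2 SD. Each epoch carries the oscillation trough (phase wrap
through π) nearest its center, used as the CSD alignment point. A
constant signal yields a warning and no epochs.

**CSD.** The event-aligned average LFP's second spatial difference
across depth-ordered channels:
`CSD(ch) = V(ch−1) − 2·V(ch) + V(ch+1)`, interior channels only.
Positive values mark current sinks — at a sink the extracellular
potential has a local depth minimum, so its second difference is
positive. The convention is declared in every `CSDMap` rather than
assumed. A depth-linear field gives exactly zero.

**Spectrogram gamma peaks.** `scipy.signal.spectrogram` with a Hamming
window of 1024 samples, overlap 512; per segment the maximum power in
30–80 Hz, in dB. Group differences use a label-shuffle null
(default 1000 permutations) with the two-sided estimator
`p = (1 + #{|null| ≥ |obs|}) / (1 + N)`, which cannot return p = 0.

**Wake scoring** is fully automatic (the original manual curation step
is irreproducible and out of scope): theta (5–11 Hz) / delta (1–4 Hz)
Welch power ratio in 2 s windows stepped by 1 s, wake when ratio > 2 or
the movement signal exceeds its own mean + 2 SD, runs shorter than 10 s
absorbed into the preceding state. All parameters are arguments.

**Reference channel**: the channel carrying the most putative-E unit
waveforms; ties broken by mean gamma wavelet amplitude.

## Phase locking (`phaselock`)

Spike phases are the band phase at the nearest 4 ms grid point (spikes
outside the decomposition span are dropped). R = |Σe^{iθ}|/n and the
circular mean; Rayleigh p uses
`p = exp(√(1 + 4n + 4(n² − Rn²)) − (1 + 2n))` with `Rn = nR`, reliable
from n ≈ 10 — below that p is NaN and the unit is not flagged.
"Modulated" means p < 0.05.

Duration matching subsamples *whole epochs* (not spikes) from the
longer condition until its total duration reaches the shorter one
(matched to within one epoch), 100 rounds; the circular mean of
per-round angles and the arithmetic mean of per-round R are reported,
with p recomputed from the averaged statistics. Whole-epoch sampling
preserves within-epoch phase structure, which spike-level subsampling
would break. Exactly equal durations skip subsampling, so the two
results are then identical by construction.

## Odor responses (`odor`)

**Inhalation onsets** (a deliberate simplification of full
breath-waveform parameterization): negative-going zero crossings of the
0.5–15 Hz band-passed pressure signal, linearly interpolated, minimum
100 ms apart.

**Evoked rates**: spikes in the 350 ms after the first inhalation with
onset ≥ odor onset, divided by 0.35 s; baseline likewise from the first
breath inside the 2 s window from 3 s to 1 s before odor onset. The
normalized rate is their ratio with the baseline floored at 0.1 Hz (the
floor prevents division blow-ups for near-silent units and is
reported).

**Cumulative surprise.** Per 10 ms bin i, the summed observed count
k_i across trials is tested against Poisson(λ_i), λ_i = summed baseline
count in the corresponding baseline-aligned bin (equivalently
trial-averaged baseline rate × Δ × n_trials — the sum-count form makes
the Poisson model exact). Activation surprise is −ln SF(k_i − 1; λ_i),
inhibition −ln CDF(k_i; λ_i), each summed over the 35 bins (natural
log; the base only rescales thresholds consistently; p floored at
1e−300). The mineral-oil control surprise, computed identically, is
subtracted per direction; the unit–odorant statistic is the larger of
the two directed values and fixes the reported direction.

**Shuffle FDR.** Each shuffle re-assigns, per trial, which of the two
windows counts as "odor" (a fair coin per trial, valid under
within-trial exchangeability), for both the odorant and the control
trials, and recomputes the identical statistic. 100 shuffles per
unit–odorant; `session_surprise` pools all of them into one null
distribution whose 95th percentile is the common threshold (5% FDR),
mirroring the pooled-null construction of the source analyses. By
exchangeability the procedure is calibrated at essentially exactly 5%
on null data — the headline calibration property the acceptance suite
checks.

**Correlations.** Signal correlation: Pearson r of trial-averaged
tuning vectors (length ≥ 3, nonzero variance; degenerate vectors raise
rather than returning NaN). Noise correlation: residuals = per-trial
response minus the across-trial mean, Pearson across time bins within
each trial, averaged over trials — the only reading that yields a
per-trial correlation to average. Note the estimator is blind to a
shared gain acting on a *flat* within-window profile (the per-trial
mean subtraction removes it); it picks up shared gain through the
temporal response profile, so analysis bins should straddle the
response window.

## Photometry (`photometry`)

ΔF/F = (F − F̄₅₀)/F̄₅₀ with a *centered sliding* 50 s mean (blockwise
was the alternative; centered windows avoid phase lag on symmetric
transients), then 20 ms moving-average smoothing, then a first-order
Butterworth 0.02 Hz high-pass applied forward–backward (zero phase
preserves event onsets). Order follows the processing description
verbatim: normalize → smooth → filter.

Event detection thresholds at center + 3 SD where center and SD are the
*median and 1.4826 × MAD* over the analysis window: a plain SD is
inflated by the transients themselves (at 6-SD amplitude and 0.33
events/s, by ~70%), which would mask the very events being counted;
robust scale estimation is standard in calcium event detection.
Excursions must stay above threshold ≥ 50 ms (suppressing single-sample
noise crossings), and events starting within 200 ms of the previous
one are absorbed. Peak heights are reported in SD units, so every event
trivially satisfies the threshold. Windows under 60 s warn that the SD
is unstable.

Odor-evoked responses are computed on the raw-F scale (the description
suggests re-normalizing to the pre-odor window rather than reusing the
processed trace): per presentation, (mean F in the 4 s window starting
1 s after onset − mean F in the 4 s before onset) / baseline, averaged
over 3 consecutive presentations; overlapping windows or fewer
presentations are errors.

## Session linkage (`linkage`)

Per-session deltas are *post − pre* (the source's verbal definition
says the opposite subtraction, but its reported signs — e.g. a decrease
printed as negative — are only consistent with post − pre, so that is
used and noted). Gamma change in dB, CCG-integral and event-rate
changes as differences. Across ≥ 4 sessions, Spearman's ρ with the
Student-t significance test and average ranks for ties
(`scipy.stats.spearmanr`).

## Synthetic generators (`synth`)

The generators state a world, they are not tuned to tests:

- `gen_spike_session`: inhomogeneous Poisson spiking by thinning at the
  maximum rate (exact, simple, seedable). Events multiply every E
  unit's rate simultaneously — matching the pooled-rate detection
  statistic. Event onsets follow a hard-core renewal process (dead time
  = duration + 100 ms, exponential waiting scaled so the onset rate is
  the requested one); explicit intervals can be planted instead.
  Defaults: 2 Hz base rate, 0.4 events/s, 150 ms, gain 5, 600 s.
- `gen_locked_spikes`: rejection sampling against the von Mises density
  of the local phase — exact for any oscillation whose phase sweeps
  uniformly.
- `gen_laminar_lfp`: amplitude profile linear from +1 (source) to −1
  (sink); optionally gated into 300 ms bursts for epoch-detection and
  aligned-CSD testing.
- `gen_odor_session`: odorants (plus a mineral-oil control) in
  randomized order, 2 s presentations, 20 s inter-stimulus, 30 trials
  per odorant by default; respiration is a ~3 Hz sinusoid with 10%
  jittered cycle periods whose negative-going zero crossings are the
  ground-truth inhalation onsets; responders multiply their rate for
  350 ms after the first inhalation in odor; a shared per-trial gain
  (clipped at 0) plants positive noise correlation.
- `gen_photometry`: transients with a 20 ms linear rise and 300 ms
  exponential decay at amplitude = `amplitude_sd_units` × noise SD,
  over Gaussian noise low-passed at ~15 Hz (so the pipeline's 20 ms
  smoothing leaves its SD nearly unchanged, keeping the planted
  SD-units interpretable), plus optional linear drift. Default sampling
  rate 1 kHz — lower than acquisition hardware, ample for 20 ms-rise
  transients and cheap enough for 10 min traces in tests.

What the generators do **not** emulate: refractory periods, bursting
and non-Poisson ISI structure, rate nonstationarity, real breath
waveform asymmetry, sniffing bouts, photobleaching curves other than
linear drift, hemodynamic/movement artifacts, or any biophysics of the
circuit. A green recovery test therefore establishes correctness of the
estimators under their own model assumptions, not robustness to every
real-world violation of them.

## Known limitations

- The surprise shuffle permutes odor-vs-baseline window labels; the
  alternative (permuting labels between odorants) was considered and
  rejected as it would not null out odor-unspecific responses.
- The CCG epoch-edge correction normalizes per lag bin, so bins can
  have different effective n; variances across bins are then unequal
  for very short epochs.
- `matched_phaselock` reports a p value recomputed from averaged
  statistics; it is a summary, not a formal test across rounds.
- Wake scoring is a deliberately simple automatic rule; it does not
  attempt to reproduce manually curated state boundaries.
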