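"""Odor responsiveness by cumulative Poisson surprise with shuffle FDR.

Generates an olfactometry session (2 s odors, 20 s inter-stimulus,
~3 Hz respiration) where 3 of 12 units triple their rate for 350 ms
after the first inhalation in odor, then scores every unit-odorant
combination and reports signal correlations between tuning vectors.
"""
import numpy as np

import popsync as ps

session = ps.synth.gen_odor_session(
    n_units=12, n_trials_per_odor=30, odorants=["iso-amyl", "benzald"],
    response_gain={0: 3.0, 1: 3.0, 2: 3.0}, seed=11,
)
onsets = ps.odor.detect_inhalation_onsets(session.respiration)
print(f"inhalation onsets detected: {onsets.size} "
      f"(~{onsets.size / session.duration:.1f} /s)")

table = ps.odor.session_surprise(session.spikes, session.trials, onsets,
                                 n_shuffles=100, fdr=0.05, seed=1)
sig = table[table.significant]
print(f"significant unit-odor combinations: {len(sig)} / {len(table)} "
      f"(threshold {table.threshold.iloc[0]:.2f} nats)")
print(sig[["unit_id", "odorant", "cumulative_surprise", "direction"]]
      .to_string(index=False))

rates = {}
for u in session.spikes:
    df = ps.odor.evoked_rates(u.spike_times, session.trials, onsets)
    rates[u.unit_id] = df.groupby("odorant")["odor_rate"].mean().to_numpy()
r01 = ps.odor.signal_correlation(rates["U000"], rates["U001"])
print(f"signal correlation U000-U001 (both responders): {r01:.2f}")
# The three planted responders are flagged 'activated' for both odorants;
# the remaining combinations stay below the pooled 95th-percentile
# shuffle threshold (5% FDR).
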