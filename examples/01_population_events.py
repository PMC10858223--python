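"""Detect synchronous population events in a spike raster.

Generates a 600 s session of 12 excitatory units firing at 2 Hz with
planted 150 ms co-activations (rate x5) at 0.4 events/s, then runs the
kernel-smoothed multiunit threshold detector and compares against the
planted truth.
"""
import numpy as np

import popsync as ps
from popsync.popevents import detect_popevents, pooled_rate, popevent_stats

session = ps.synth.gen_spike_session(
    n_excitatory=12, duration=600.0, base_rate=2.0,
    popevent_rate=0.4, popevent_duration=0.15, popevent_gain=5.0, seed=7,
)
epochs = ps.EventIntervalSet([[0.0, 600.0]], label="wake")

rate = pooled_rate(session.spikes.select("E"), 600.0)
events = detect_popevents(rate, epochs)
ev_rate, pct_time, pct_spikes = popevent_stats(events, epochs, session.spikes)

print(f"planted events : {session.truth.popevent_intervals.shape[0]} "
      f"({session.truth.popevent_intervals.shape[0] / 600:.3f} /s)")
print(f"detected events: {len(events)} ({ev_rate:.3f} /s)")
print(f"mean duration  : {events.durations.mean() * 1000:.0f} ms")
print(f"time in events : {pct_time:.1f} %   spikes in events: {pct_spikes:.1f} %")
# The detected rate should sit within ~10% of the planted 0.4 events/s;
# events occupy a few percent of time but a much larger share of spikes —
# the signature of transient population synchrony.
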