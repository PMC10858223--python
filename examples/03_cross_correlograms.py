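"""Rate-normalized cross-correlograms and the effect of excluding
population events.

Two units that co-fire only inside planted population events show a
central CCG peak; removing in-event spikes flattens the correlogram back
to the independence level of 1.
"""
import numpy as np

import popsync as ps
from popsync.paircorr import ccg_peak_integral, compute_ccg
from popsync.popevents import exclude_event_spikes

session = ps.synth.gen_spike_session(
    n_excitatory=12, duration=600.0, base_rate=2.0,
    popevent_rate=0.4, popevent_gain=8.0, seed=3,
)
epochs = ps.EventIntervalSet([[0.0, 600.0]])
events = ps.EventIntervalSet(session.truth.popevent_intervals, label="popevent")

a = session.spikes[0].spike_times
b = session.spikes[1].spike_times

full = compute_ccg(a, b, epochs)
print(f"with events   : mean bin {np.nanmean(full.values):.3f}, "
      f"peak integral {ccg_peak_integral(full) * 1000:.2f} x10^-3")

a_out = exclude_event_spikes(a, events)
b_out = exclude_event_spikes(b, events)
clean = compute_ccg(a_out, b_out, epochs)
print(f"events removed: mean bin {np.nanmean(clean.values):.3f}, "
      f"peak integral {ccg_peak_integral(clean) * 1000:.2f} x10^-3")
# The peak integral (excess coincidence in +-50 ms over the outer-lag
# baseline) collapses toward 0 once in-event spikes are excluded: the
# pairwise correlation lives in the population events.
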