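"""Simulate ACAN behaviour presets and check their firing signatures.

Each of the 20 presets (labels "a".."t") is a digital neuron built from
four shift registers.  After settling at zero drive, each preset is driven
with its default stimulus protocol and its qualitative firing pattern is
summarised.
"""

import numpy as np

from acanet import preset_params, simulate
from acanet.pipeline import reproduce_patterns

# A tonic spiker under sustained drive: settle first, then a step input.
params = preset_params("a", R=64)
settle = simulate(params, np.zeros(100))
trace = simulate(params, np.full(200, 15.0), settle.final_state)
print(f"type a, step drive 15: {trace.spike_count} spikes at {trace.spike_times[:6]}...")

# An inhibition-induced burster: fires only under negative drive.
params_t = preset_params("t", R=64)
settle_t = simulate(params_t, np.zeros(100))
rest = simulate(params_t, np.zeros(200), settle_t.final_state)
inh = simulate(params_t, np.full(200, -4.0), settle_t.final_state)
print(f"type t: {rest.spike_count} spikes at rest, {inh.spike_count} under drive -4")

# Full report across all 20 presets with their default protocols.
report = reproduce_patterns()
print(report.to_string(index=False))
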