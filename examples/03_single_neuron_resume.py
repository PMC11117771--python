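"""Teach one ACAN a periodic spike train with the digital ReSuMe rule.

A fixed sparse Poisson input drives a single neuron; the remote-supervision
update pulls the output train toward a periodic target.  The mismatched-bin
distance between the actual and desired trains shrinks over epochs.
"""

from acanet.pipeline import single_neuron_demo

res = single_neuron_demo(seed=0)
print(f"target period: {res['target_period']} steps")
print(f"mismatched bins per epoch: {res['mismatch_log']}")
print(
    f"initial {res['initial']}, minimum {res['minimum']}, final {res['final']} "
    f"({100 * (res['initial'] - res['minimum']) / res['initial']:.0f}% drop)"
)
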