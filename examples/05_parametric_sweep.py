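"""Sweep neuron type, register size and learning-window time constant.

A small grid over ACAN preset x R x tau is trained and evaluated on a tiny
synthetic spike dataset to show how the sweep table is produced.
"""

from acanet.learning import ReSuMeConfig
from acanet.movement import generate_synthetic_dataset
from acanet.network import NetworkConfig, parametric_sweep
from acanet.neuron import preset_params
from acanet.pipeline import build_spike_dataset, stratified_split, windows_from_samples

samples = generate_synthetic_dataset(n_per_class=2, F=200, seed=0)
windows = windows_from_samples(samples, S=100, stride=10, seed=1)
tr_w, te_w = stratified_split(windows, 0.8, seed=2)
train_data, stats = build_spike_dataset(tr_w, seed=3)
test_data, _ = build_spike_dataset(te_w, seed=4, stats=stats)

base = NetworkConfig(
    n_inputs=train_data[0][0].shape[0],
    n_classes=5,
    acan=preset_params("a", 64),
    resume=ReSuMeConfig(lr=0.0001, alpha=1.0, tau=15.0),
    S=100,
    epochs=5,
    seed=0,
)
table = parametric_sweep(["a", "c"], [32, 64], [5.0, 15.0], train_data, test_data, base)
print(table.to_string(index=False))
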