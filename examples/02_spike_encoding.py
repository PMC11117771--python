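"""Turn continuous features into Poisson spike trains.

Features are min-max scaled per channel into [0, 1] firing rates, optionally
augmented with finite-difference velocities, and drawn into Bernoulli spikes.
"""

import numpy as np

from acanet import kinematic_augment, normalize_minmax, poisson_encode

rng = np.random.default_rng(0)
positions = np.cumsum(rng.normal(0, 0.01, (4, 200)), axis=1)  # 4 channels, 200 frames

augmented = kinematic_augment(positions, order=1)  # + velocities -> 8 channels
rates, stats = normalize_minmax(augmented)
spikes = poisson_encode(rates, seed=42)

print(f"channels: {positions.shape[0]} -> {augmented.shape[0]} after augmentation")
print(f"rate range: [{rates.min():.3f}, {rates.max():.3f}]")
print(f"mean programmed rate {rates.mean():.3f}, empirical spike fraction {spikes.mean():.3f}")

# Held-out data reuses the training statistics and is clipped into [0, 1].
held_out = kinematic_augment(positions * 1.5, order=1)
rates2, _ = normalize_minmax(held_out, stats=stats)
print(f"held-out rates stay in [{rates2.min():.3f}, {rates2.max():.3f}] after clipping")
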