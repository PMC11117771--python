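# Methods

This note records the exact semantics of the implemented model, the
design decisions taken where a purely digital formulation admits more
than one reading, and the known limitations.

## 1. ACAN neuron

### State and parameters

A neuron's state is four bounded integers: membrane `V ∈ {0..N−1}`,
recovery `U ∈ {0..M−1}`, and velocity counters `P ∈ {0..K−1}`,
`Q ∈ {0..J−1}`. Parameters are the nine hyper-parameters
`γ1..γ5, λ, μ, ρ1, ρ2` plus the four register lengths. All presets use a
uniform register length `N = M = K = J = R` and `λ = R`.

### Vector field

At a state `(V, U)` the normalised two-variable field is

```
F(V, U) = N · (γ1 (V/N − γ2)² + γ3 − U/M) / λ
G(V, U) = μ · M · (γ4 (V/N − γ2) + (γ3 + γ5) − U/M) / λ
```

This is the Izhikevich quadratic-plus-linear form expressed over the
register ranges.

### Periods, directions, tick

The counter periods are the reciprocal field magnitudes,

```
Ph = max(⌊|1/F|⌋ − 1, 0)     (∞ when F = 0; likewise Qh from G)
```

so a strong field gives period 0 (shift every tick) and a weak field a
long period. Shift directions are `sgn F` and `sgn G`.

One internal tick proceeds in this order:

1. `P ← min(P+1, K−1)`, `Q ← min(Q+1, J−1)` (saturating increment);
2. periods and directions are evaluated **at the post-increment,
   pre-shift state**;
3. if `P ≥ Ph`: `P ← 0`, `V` shifts one place (saturating at 0 and
   `N−1`); independently for `Q/U`;
4. if `V = N−1` the neuron fires: `V ← A = ⌊ρ1 N⌋`,
   `U ← clip(U + ⌊ρ2 M⌋, 0, M−1)`.

A *simulation step* applies the external stimulus once —
`V ← clip(V + round(stim), 0, N−1)` — and then runs `ticks_per_step`
internal ticks (default `N`, i.e. the membrane can traverse its whole
register within one step). A step's spike output is 1 if any of its
ticks fired.

Design decisions worth noting:

- **Reciprocal period.** `Ph = ⌊|1/F|⌋ − 1` (clipped at 0) encodes
  "larger field → shorter period". A zero field freezes the variable
  (infinite period), which creates true fixed points.
- **Reset `B` is computed from the current `U`**, i.e. after any shift
  that happened earlier in the same tick, then clipped into the
  register.
- **Firing condition** is `V` at the ceiling `N−1` after the shift
  phase, checked once per tick.

Two implementations exist: a pure-Python reference (`tick`,
`simulate_reference`) defining the semantics, and a numba kernel
(`simulate`, `simulate_bank_kernel`) verified bit-for-bit against it.

### Presets and behaviour reproduction

`acanet/data/presets.yaml` holds the twenty rows `a`–`t`
(`γ1..γ5, μ, ρ1, ρ2`). Rows `a` and `b` (tonic vs phasic spiking) share
the same parameter vector; the distinction lies in the stimulus
protocol, not the parameters.

`pipeline.reproduce_patterns` drives every preset with a default
protocol (sustained step, single pulse, or a finite inhibitory episode)
after 100 zero-drive settling steps — all presets settle to silence from
the rest-like start `(A, 0, 0, 0)`. Protocol amplitudes are expressed in
membrane-register units and were calibrated once for `R = 64`; at other
register sizes the amplitudes scale with the register and must be passed
explicitly. Eight highlighted types carry checkable signature
predicates (count/ordering properties, not waveform matches): tonic
spiking (a), bursting (c), adaptation (f), class-1 rate increase (g),
subthreshold oscillation (j), rebound spike (m), inhibition-induced
spiking/bursting (s/t).

## 2. Digital ReSuMe

For desired and actual binary output trains `Sd, Sl ∈ {0,1}^(outputs×S)`
and input trains `Sin ∈ {0,1}^(inputs×S)`, the batch update over one
sample is

```
trace = Sin · Tᵀ,  T lower-triangular Toeplitz of LW[Δt] = e^(−Δt/τ)
Δw    = lr · (Sd − Sl) · (α + trace)ᵀ
```

`α` is the non-Hebbian term, `trace` the causal eligibility of each
input at each step. A missed desired spike (`Sd=1, Sl=0`) potentiates;
a spurious spike depresses. `Sl = Sd` is an exact fixed point. The
vectorised form is verified against a naive per-(output, input, step)
loop to ≤1e−12.

### Single-neuron convergence settings

Teaching one neuron an exact spike *timing* needs a learning window
sharp relative to the target period: with τ much larger than the period
the trace is nearly flat over a period and only steers the firing rate.
`fit_single_neuron` therefore defaults to a small neuron (preset a,
R=16), τ=1, α=0.05, lr=0.05, with sparse inputs; the classifier uses the
rate-steering regime (τ=15, α=1, lr=0.0001) where only spike counts
matter.

## 3. Encoding

- Per-channel min-max scaling to `[0, 1]`; train-time `(lo, hi)` stats
  are replayed on held-out data and the result is clipped. Constant
  channels map to rate 0.
- Optional kinematic augmentation appends finite-difference velocities
  (edge-replicated first column), doubling 114 position channels to 228.
- Poisson (Bernoulli-per-step) coding: a spike is drawn iff
  `u ≤ rate` and `rate > 0`, with one RNG sub-seed per window so a
  dataset is reproducible from a single seed.

Two layouts map a feature window to network input: `time-series`
(channels × S, the default) keeps each frame as a time step;
`per-feature` flattens every (channel, frame) cell into its own input
row with a constant rate over a short train, as pixels are usually
rate-coded.

## 4. Network and training

One ACAN per class receives the stimulus `w · Sin(t)`; all neurons start
from the rest-like state for every sample. The desired train of the true
class is periodic (default period 4); other rows are silent. Training is
online: for each sample, forward simulate, log whether the pre-update
prediction was correct, then apply the ReSuMe update. Sample order is
reshuffled each epoch from a derived seed. Readout is spike-count
argmax (a softmax score over counts is also reported; the argmax is
identical). Accuracy is correct/total.

`parametric_sweep` trains one configuration per (type, R, τ) grid cell
and tabulates train/test accuracy.

## 5. Movement pipeline

Recordings are 38 markers × 3 coordinates per frame (114 channels). A
sliding window `[f, f+S−1]` is labelled with the recording's movement
class iff it intersects the recording's critical area (closed frame
interval); otherwise it is labelled gait. Gait recordings have no
critical area. Classes are balanced by seeded downsampling to the
smallest class. The end-to-end experiment (`run_experiment`) splits
windows 90/10 stratified, computes normalisation stats on the training
windows only, and derives all sub-seeds (generator, balancing, split,
encoding, training) from one run seed.

### Synthetic generator and its realism limits

Because the original recordings are unavailable, a seeded generator
produces all five classes from a standing marker template (head, torso,
pelvis, arm and leg groups) with: sinusoidal limb oscillation and
constant forward drift for gait (step cycle 100 frames, 0.012 m/frame);
a lateral smoothstep plus zigzag for cutting; a 90° rotation about the
pelvis for turning; ±0.45 m vertical smoothstep with damped gait for
sitting down / standing up; and additive Gaussian marker noise
(default SD 5 mm). Critical areas are placed mid-sample for cutting and
turning and at onset for the two transfers.

Limits: the kinematics are schematic (no inverse kinematics, no ground
contact, no inter-subject variability, no soft-tissue artefact); class
difficulty is therefore not calibrated to real motion capture, and
accuracies on this data are a property of the generator + pipeline, not
a clinical claim. Problem sizes (windows per class, frames per
recording, number of recordings) are package choices made for desk-scale
runtimes.

## 6. Numerical choices

- All register dynamics are exact integer arithmetic; the only floating
  point is in the vector field, the learning window and the weights.
- The numba kernels are deterministic and compiled with `cache=True`;
  first use incurs a one-time JIT cost.
- All randomness flows through `numpy.random.default_rng` with derived
  sub-seeds (< 2³¹), so every figure in the README and every test value
  is reproducible bit for bit.

## 7. Limitations

- Accuracy on the synthetic task varies noticeably with the seed
  (observed 0.63–0.85 test accuracy at the default configuration);
  single runs should not be over-interpreted.
- Behaviour-signature protocols are calibrated for R=64; other register
  sizes need rescaled amplitudes.
- The phasic/one-spike preset variants share parameters with their tonic
  counterparts and are distinguished only by protocol, so they carry no
  independent parametric check.
- Hardware aspects of the architecture (bit-serial implementation,
  resource/energy figures) are out of scope; this package is a software
  model.
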