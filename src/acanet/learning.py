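"""Digital ReSuMe: supervised spike-train learning with a precomputed
exponential window.

The remote supervised method drives a neuron's output spike train Sl
toward a desired train Sd by Hebbian-style weight changes gated on the
per-step spike difference.  In this discrete formulation the learning
window LW[Δt] = exp(−Δt/τ) is tabulated once, every input channel's spike
train is convolved with it causally to form an eligibility trace, and the
whole update collapses to one matrix product:

    Δw[o, i] = lr · Σ_t (Sd − Sl)[o, t] · (α + trace[i, t])

A desired spike the neuron missed potentiates the synapses whose inputs
fired recently (and by the flat amount α regardless of input history); a
spurious output spike depresses them symmetrically; a matched spike
changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "LearningWindow",
    "ReSuMeConfig",
    "spike_diff_signal",
    "build_learning_window",
    "input_trace",
    "resume_update",
    "resume_update_reference",
]


@dataclass(frozen=True)
class LearningWindow:
    """Tabulated exponential kernel LW[Δt] = e^(−Δt/τ), Δt = 0..S−1."""

    LW: np.ndarray
    tau: float

    def __len__(self) -> int:
        return len(self.LW)


@dataclass(frozen=True)
class ReSuMeConfig:
    """Learning hyper-parameters: rate lr, non-correlation amplitude alpha,
    window time constant tau, and optional weight bounds."""

    lr: float = 0.0001
    alpha: float = 1.0
    tau: float = 15.0
    w_min: Optional[float] = None
    w_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def spike_diff_signal(Sl: np.ndarray, Sd: np.ndarray) -> np.ndarray:
    """Per-step spike difference between output train Sl and desired Sd.

    Returns +1 where Sl spikes alone, −1 where Sd spikes alone, 0 where
    both or neither spike.  (The weight update uses the opposite sign,
    Sd − Sl, so that a missed desired spike potentiates.)
    """
    Sl = np.asarray(Sl)
    Sd = np.asarray(Sd)
    if Sl.shape != Sd.shape:
        raise ValueError(f"spike train shapes differ: {Sl.shape} vs {Sd.shape}")
    return (Sl - Sd).astype(np.int64)


def build_learning_window(tau: float, S: int) -> LearningWindow:
    """Tabulate LW[Δt] = e^(−Δt/τ) for Δt = 0..S−1."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if S < 1:
        raise ValueError("S must be >= 1")
    dt = np.arange(S, dtype=np.float64)
    return LearningWindow(LW=np.exp(-dt / tau), tau=float(tau))


def _window_matrix(LW: np.ndarray, S: int) -> np.ndarray:
    """Lower-triangular (S, S) Toeplitz T with T[t, t'] = LW[t−t'] for t' ≤ t."""
    col = np.zeros(S)
    k = min(S, len(LW))
    col[:k] = LW[:k]
    return toeplitz(col, np.zeros(S))


def input_trace(Sin: np.ndarray, window: LearningWindow) -> np.ndarray:
    """Causal eligibility trace of each input channel.

    trace[c, t] = Σ_{t' ≤ t, Sin[c, t']=1} LW[t − t'] — the superposition of
    one decaying exponential per past (or current) input spike.
    """
    Sin = np.atleast_2d(np.asarray(Sin, dtype=np.float64))
    S = Sin.shape[1]
    T = _window_matrix(window.LW, S)
    return Sin @ T.T


def resume_update(
    w: np.ndarray,
    Sd: np.ndarray,
    Sl: np.ndarray,
    Sin: np.ndarray,
    cfg: ReSuMeConfig,
    window: LearningWindow,
) -> np.ndarray:
    """One vectorised ReSuMe step over a whole sample of S time steps.

    w is (outputs, inputs); Sd and Sl are (outputs, S) desired and actual
    output trains; Sin is (inputs, S).  Returns the updated weight matrix
    (the input is not modified).
    """
    w = np.asarray(w, dtype=np.float64)
    Sd = np.atleast_2d(np.asarray(Sd, dtype=np.float64))
    Sl = np.atleast_2d(np.asarray(Sl, dtype=np.float64))
    Sin = np.atleast_2d(np.asarray(Sin, dtype=np.float64))
    n_out, n_in = w.shape
    if Sd.shape != Sl.shape:
        raise ValueError(f"Sd/Sl shapes differ: {Sd.shape} vs {Sl.shape}")
    if Sd.shape[0] != n_out:
        raise ValueError(f"Sd has {Sd.shape[0]} rows for {n_out} output neurons")
    if Sin.shape[0] != n_in:
        raise ValueError(f"Sin has {Sin.shape[0]} rows for {n_in} input channels")
    if Sd.shape[1] != Sin.shape[1]:
        raise ValueError("output and input trains must cover the same steps")
    diff = Sd - Sl  # desired-minus-actual: missed spikes potentiate
    trace = input_trace(Sin, window)
    w_new = w + cfg.lr * diff @ (cfg.alpha + trace).T
    if cfg.w_min is not None or cfg.w_max is not None:
        w_new = np.clip(w_new, cfg.w_min, cfg.w_max)
    return w_new


def resume_update_reference(
    w: np.ndarray,
    Sd: np.ndarray,
    Sl: np.ndarray,
    Sin: np.ndarray,
    cfg: ReSuMeConfig,
    window: LearningWindow,
) -> np.ndarray:
    """Per-spike scalar-loop reference for the vectorised update.

    Accumulates lr · diff[o, t] · (α + Σ_{t' ≤ t} Sin[i, t'] · LW[t − t'])
    with explicit loops over (output, input, step).  Kept deliberately
    naive; used to cross-check :func:`resume_update`.
    """
    w = np.array(w, dtype=np.float64, copy=True)
    Sd = np.atleast_2d(Sd)
    Sl = np.atleast_2d(Sl)
    Sin = np.atleast_2d(Sin)
    n_out, n_in = w.shape
    S = Sd.shape[1]
    LW = window.LW
    for o in range(n_out):
        for t in range(S):
            diff = float(Sd[o, t]) - float(Sl[o, t])
            if diff == 0.0:
                continue
            for i in range(n_in):
                acc = 0.0
                for tp in range(t + 1):
                    if Sin[i, tp]:
                        acc += LW[t - tp]
                w[o, i] += cfg.lr * diff * (cfg.alpha + acc)
    if cfg.w_min is not None or cfg.w_max is not None:
        w = np.clip(w, cfg.w_min, cfg.w_max)
    return w
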