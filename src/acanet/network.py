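"""One-layer spiking classifier: rate-coded input → one ACAN per class →
spike-count/argmax readout, trained with digital ReSuMe.

Each class neuron receives the weighted sum of all input spike channels as
its per-step stimulus.  During training the true class's neuron is given a
periodic desired train (and the others silence); after each sample the
weights move by one ReSuMe step.  Prediction takes the neuron with the
most output spikes over the sample (softmax over counts is reported as a
score but is argmax-equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import simulate_bank_kernel
from .learning import ReSuMeConfig, build_learning_window, resume_update
from .neuron import ACANParams, default_initial_state, preset_params

__all__ = [
    "NetworkConfig",
    "ClassifierOutput",
    "make_target_trains",
    "init_weights",
    "forward",
    "train",
    "evaluate",
    "fit_single_neuron",
    "confusion_matrix",
    "parametric_sweep",
]


@dataclass
class NetworkConfig:
    """Architecture and training settings of the classifier.

    One ACAN per class, all sharing ``acan``'s parameters; ``S`` is the
    number of time steps per sample and ``target_period`` the spacing of
    the desired train's spikes for the true class.
    """

    n_inputs: int
    n_classes: int
    acan: ACANParams = field(default_factory=lambda: preset_params("a", 64))
    resume: ReSuMeConfig = field(default_factory=ReSuMeConfig)
    S: int = 100
    target_period: int = 4
    epochs: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.S < 1 or self.target_period < 1:
            raise ValueError("S and target_period must be positive")


@dataclass(frozen=True)
class ClassifierOutput:
    """Forward-pass result: per-class output trains, spike counts, softmax
    scores, and the predicted label (argmax, lowest index on ties)."""

    spike_trains: np.ndarray  # (n_classes, S) binary
    counts: np.ndarray  # (n_classes,)
    scores: np.ndarray  # (n_classes,) softmax of counts
    label: int


def make_target_trains(label: int, cfg: NetworkConfig) -> np.ndarray:
    """Desired output trains: the true class spikes every ``target_period``
    steps starting at t=0; all other classes stay silent."""
    if not 0 <= label < cfg.n_classes:
        raise ValueError(f"label {label} out of range [0, {cfg.n_classes})")
    Sd = np.zeros((cfg.n_classes, cfg.S), dtype=np.int8)
    Sd[label, :: cfg.target_period] = 1
    return Sd


def init_weights(cfg: NetworkConfig) -> np.ndarray:
    """Uniform init on [0, 1/n_inputs], seeded from the config."""
    rng = np.random.default_rng(cfg.seed)
    return rng.uniform(0.0, 1.0 / cfg.n_inputs, size=(cfg.n_classes, cfg.n_inputs))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def forward(spikes: np.ndarray, w: np.ndarray, cfg: NetworkConfig) -> ClassifierOutput:
    """Run one sample through the classifier.

    ``spikes`` is (n_inputs, S); each class neuron's stimulus at step t is
    Σ_i w[o, i]·spikes[i, t].  Neurons start from the rest-like state
    (V=A, U=P=Q=0) so samples are independent.
    """
    spikes = np.asarray(spikes)
    if spikes.shape != (cfg.n_inputs, spikes.shape[1]):
        raise ValueError(f"spikes must be ({cfg.n_inputs}, S), got {spikes.shape}")
    if w.shape != (cfg.n_classes, cfg.n_inputs):
        raise ValueError(
            f"weights must be ({cfg.n_classes}, {cfg.n_inputs}), got {w.shape}"
        )
    stimuli = np.ascontiguousarray(w @ spikes, dtype=np.float64)
    p = cfg.acan
    s0 = default_initial_state(p)
    Y = simulate_bank_kernel(
        stimuli,
        p.gamma1, p.gamma2, p.gamma3, p.gamma4, p.gamma5,
        p.lam, p.mu, p.rho1, p.rho2,
        p.N, p.M, p.K, p.J, p.ticks_per_step,
        s0.V, s0.U, s0.P, s0.Q,
    )
    counts = Y.sum(axis=1)
    return ClassifierOutput(
        spike_trains=Y,
        counts=counts,
        scores=_softmax(counts.astype(np.float64)),
        label=int(np.argmax(counts)),
    )


def train(
    dataset: Sequence[tuple[np.ndarray, int]],
    cfg: NetworkConfig,
    w0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list[float]]:
    """Online ReSuMe training over ``cfg.epochs`` passes.

    For every sample the forward pass runs first and its pre-update
    correctness feeds the epoch's training accuracy (the sample is
    effectively unseen at that moment, even in epoch one); the weight
    update against the periodic target trains follows.  Samples are
    reshuffled each epoch with a seed derived from ``cfg.seed``.
    Returns the trained weights and the per-epoch accuracy log.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    w = init_weights(cfg) if w0 is None else np.array(w0, dtype=np.float64)
    window = build_learning_window(cfg.resume.tau, cfg.S)
    targets = [make_target_trains(k, cfg) for k in range(cfg.n_classes)]
    log: list[float] = []
    order_rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(cfg.epochs):
        order = order_rng.permutation(len(dataset))
        correct = 0
        for idx in order:
            spikes, label = dataset[idx]
            out = forward(spikes, w, cfg)
            if out.label == label:
                correct += 1
            w = resume_update(w, targets[label], out.spike_trains, spikes, cfg.resume, window)
        log.append(correct / len(dataset))
    return w, log


def evaluate(
    dataset: Sequence[tuple[np.ndarray, int]],
    w: np.ndarray,
    cfg: NetworkConfig,
) -> float:
    """Classification accuracy = correct / total over the given samples."""
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    correct = sum(forward(s, w, cfg).label == y for s, y in dataset)
    return correct / len(dataset)


def fit_single_neuron(
    Sin: np.ndarray,
    Sd: np.ndarray,
    params: Optional[ACANParams] = None,
    cfg: Optional[ReSuMeConfig] = None,
    epochs: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Teach one ACAN to reproduce a desired spike train from fixed input.

    ``Sin`` is (n_inputs, S), ``Sd`` a length-S binary target.  Each epoch
    runs the neuron on the weighted input and applies one ReSuMe step; the
    returned log holds the per-epoch mismatched-bin count (Hamming distance
    between the output and the target, measured before that epoch's
    update).

    Defaults differ from the classifier's: a small register (R=16) keeps
    the neuron responsive to few-unit stimulus kicks, and a sharp window
    (τ=1) with a larger rate (lr=0.05) resolves spike timing at the level
    of single bins — a wide window can only steer the firing rate, not the
    phase.
    """
    params = params if params is not None else preset_params("a", 16)
    cfg = cfg if cfg is not None else ReSuMeConfig(lr=0.05, alpha=0.05, tau=1.0)
    Sin = np.atleast_2d(np.asarray(Sin))
    Sd = np.atleast_2d(np.asarray(Sd))
    n_in, S = Sin.shape
    window = build_learning_window(cfg.tau, S)
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0 / n_in, size=(1, n_in))
    s0 = default_initial_state(params)
    log: list[int] = []
    for _ in range(epochs):
        stim = np.ascontiguousarray(w @ Sin, dtype=np.float64)
        Y = simulate_bank_kernel(
            stim,
            params.gamma1, params.gamma2, params.gamma3, params.gamma4, params.gamma5,
            params.lam, params.mu, params.rho1, params.rho2,
            params.N, params.M, params.K, params.J, params.ticks_per_step,
            s0.V, s0.U, s0.P, s0.Q,
        )
        log.append(int(np.sum(Y != Sd)))
        w = resume_update(w, Sd, Y, Sin, cfg, window)
    return w, log


def confusion_matrix(
    dataset: Sequence[tuple[np.ndarray, int]],
    w: np.ndarray,
    cfg: NetworkConfig,
) -> np.ndarray:
    """(true, predicted) count matrix over the dataset."""
    cm = np.zeros((cfg.n_classes, cfg.n_classes), dtype=np.int64)
    for spikes, label in dataset:
        cm[label, forward(spikes, w, cfg).label] += 1
    return cm


def parametric_sweep(
    types: Sequence[str],
    R_values: Sequence[int],
    tau_values: Sequence[float],
    train_data: Sequence[tuple[np.ndarray, int]],
    test_data: Sequence[tuple[np.ndarray, int]],
    base_cfg: NetworkConfig,
) -> pd.DataFrame:
    """Grid sweep over (ACAN type, register size R, window constant τ).

    Every combination retrains from scratch with the base config's other
    settings; the returned table has one row per combination with the final
    train accuracy and test accuracy, sorted as generated.  The best row by
    test accuracy is the recommended configuration.
    """
    rows = []
    for type_label, R, tau in product(types, R_values, tau_values):
        cfg = NetworkConfig(
            n_inputs=base_cfg.n_inputs,
            n_classes=base_cfg.n_classes,
            acan=preset_params(type_label, R),
            resume=ReSuMeConfig(lr=base_cfg.resume.lr, alpha=base_cfg.resume.alpha, tau=tau),
            S=base_cfg.S,
            target_period=base_cfg.target_period,
            epochs=base_cfg.epochs,
            seed=base_cfg.seed,
        )
        w, log = train(train_data, cfg)
        rows.append(
            {
                "type": type_label,
                "R": R,
                "tau": tau,
                "train_accuracy": log[-1],
                "test_accuracy": evaluate(test_data, w, cfg),
            }
        )
    return pd.DataFrame(rows)
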