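"""Asynchronous cellular automaton-based neuron (ACAN).

The neuron's state lives in four bidirectional shift registers:

* membrane register  V ∈ {0..N−1}   — discrete membrane potential,
* recovery register  U ∈ {0..M−1}   — discrete recovery variable,
* velocity counters  P ∈ {0..K−1}, Q ∈ {0..J−1} — gate how often V and U
  move.

A memoryless vector-field unit evaluates the Izhikevich-like pair

    F(V, U) = N (γ1 (V/N − γ2)² + γ3 − U/M) / λ
    G(V, U) = μ M (γ4 (V/N − γ2) + (γ3 + γ5) − U/M) / λ

whose signs give the shift directions of V and U and whose magnitudes set
the counter periods Ph = ⌊|1/F|⌋ − 1 (clipped to ≥ 0; infinite when F = 0)
and Qh analogously: a fast vector field means a short period and hence a
fast-moving register.  When V climbs to the register ceiling N−1 the neuron
emits a spike and a rest-value unit resets the state to

    A = ⌊ρ1 N⌋,   B = clip(U + ⌊ρ2 M⌋, 0, M−1).

Twenty behaviour presets labelled ``a``..``t`` cover the canonical cortical
firing patterns (tonic/phasic spiking and bursting, adaptation, rebound,
inhibition-induced firing, ...); see :data:`PRESET_LABELS` and
:func:`preset_params`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from ._kernels import simulate_kernel

__all__ = [
    "ACANParams",
    "ACANState",
    "ControlSignals",
    "NeuronTrace",
    "PRESET_LABELS",
    "INFINITE",
    "preset_params",
    "eval_vector_field",
    "eval_periods",
    "eval_directions",
    "eval_reset",
    "tick",
    "simulate",
]

#: Sentinel for an infinite counter period (vector field exactly zero).
INFINITE = math.inf


@dataclass(frozen=True)
class ACANParams:
    """Full hyper-parameter set of one ACAN.

    ``gamma1..gamma5`` shape the vector field, ``lam`` (λ > 0) divides both
    field components and thus sets the overall speed, ``mu`` scales the
    recovery dynamics (negative for the inhibition-driven types), and
    ``rho1``/``rho2`` parameterise the post-spike reset.  ``N, M, K, J`` are
    the register sizes (number of representable states) and
    ``ticks_per_step`` is the number of internal clock ticks run per
    external time step.
    """

    gamma1: float
    gamma2: float
    gamma3: float
    gamma4: float
    gamma5: float
    lam: float
    mu: float
    rho1: float
    rho2: float
    N: int
    M: int
    K: int
    J: int
    ticks_per_step: int = 0  # 0 -> defaults to N in __post_init__

    def __post_init__(self) -> None:
        if self.ticks_per_step == 0:
            object.__setattr__(self, "ticks_per_step", self.N)
        for name in ("N", "M", "K", "J"):
            if getattr(self, name) < 2:
                raise ValueError(f"register size {name} must be >= 2")
        if self.lam == 0:
            raise ValueError("lam must be nonzero")
        if not 0 <= self.rho1 < 1:
            raise ValueError("rho1 must lie in [0, 1) so the reset value stays in the register")
        if self.ticks_per_step < 1:
            raise ValueError("ticks_per_step must be >= 1")

    @property
    def reset_values(self) -> tuple[int, int]:
        """(A, B-offset base): A = floor(rho1*N); B is state dependent."""
        return int(math.floor(self.rho1 * self.N)), int(math.floor(self.rho2 * self.M))

    def with_(self, **kwargs) -> "ACANParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ACANState:
    """Instantaneous register contents (V, U, P, Q)."""

    V: int
    U: int
    P: int = 0
    Q: int = 0

    def validate(self, params: ACANParams) -> "ACANState":
        if not (0 <= self.V <= params.N - 1):
            raise ValueError(f"V={self.V} outside membrane register [0, {params.N - 1}]")
        if not (0 <= self.U <= params.M - 1):
            raise ValueError(f"U={self.U} outside recovery register [0, {params.M - 1}]")
        if not (0 <= self.P <= params.K - 1):
            raise ValueError(f"P={self.P} outside counter register [0, {params.K - 1}]")
        if not (0 <= self.Q <= params.J - 1):
            raise ValueError(f"Q={self.Q} outside counter register [0, {params.J - 1}]")
        return self


@dataclass(frozen=True)
class ControlSignals:
    """Shift-enable and direction signals produced by the vector-field unit."""

    sV: int
    sU: int
    deltaV: int
    deltaU: int


@dataclass(frozen=True)
class NeuronTrace:
    """Per-step record of a simulation: membrane value and output spikes.

    ``final_state`` carries the register contents after the last step so
    that protocols can be chained (e.g. settle at rest, then stimulate).
    """

    V_trace: np.ndarray  # int, shape (T,)
    Y: np.ndarray  # binary int, shape (T,)
    final_state: Optional["ACANState"] = None

    def __post_init__(self) -> None:
        if len(self.V_trace) != len(self.Y):
            raise ValueError("V_trace and Y must have equal length")

    @property
    def spike_times(self) -> np.ndarray:
        return np.flatnonzero(self.Y)

    @property
    def spike_count(self) -> int:
        return int(self.Y.sum())


PRESET_LABELS: tuple[str, ...] = tuple("abcdefghijklmnopqrst")

_PRESET_TABLE: Optional[dict] = None


def _preset_table() -> dict:
    global _PRESET_TABLE
    if _PRESET_TABLE is None:
        text = resources.files("acanet.data").joinpath("presets.yaml").read_text()
        _PRESET_TABLE = yaml.safe_load(text)
    return _PRESET_TABLE


def preset_params(type_label: str, R: int, ticks_per_step: int = 0) -> ACANParams:
    """Instantiate a behaviour preset with uniform registers of size ``R``.

    ``type_label`` is one of ``a``..``t``; λ is set to R and N = M = K = J = R.
    """
    table = _preset_table()
    if type_label not in table:
        raise KeyError(
            f"unknown ACAN type {type_label!r}; valid labels are "
            f"{', '.join(PRESET_LABELS)}"
        )
    if R < 2:
        raise ValueError("register size R must be >= 2")
    row = table[type_label]
    g1, g2, g3, g4, g5 = (float(g) for g in row["gamma"])
    return ACANParams(
        gamma1=g1, gamma2=g2, gamma3=g3, gamma4=g4, gamma5=g5,
        lam=float(R), mu=float(row["mu"]),
        rho1=float(row["rho1"]), rho2=float(row["rho2"]),
        N=R, M=R, K=R, J=R,
        ticks_per_step=ticks_per_step,
    )


def eval_vector_field(state: ACANState, params: ACANParams) -> tuple[float, float]:
    """Evaluate (F, G) at the given register state."""
    p = params
    v = state.V / p.N
    u = state.U / p.M
    F = p.N * (p.gamma1 * (v - p.gamma2) ** 2 + p.gamma3 - u) / p.lam
    G = p.mu * p.M * (p.gamma4 * (v - p.gamma2) + (p.gamma3 + p.gamma5) - u) / p.lam
    return F, G


def _period(x: float) -> float:
    if x == 0.0:
        return INFINITE
    return max(math.floor(abs(1.0 / x)) - 1.0, 0.0)


def eval_periods(state: ACANState, params: ACANParams) -> tuple[float, float]:
    """Counter periods (Ph, Qh) = ⌊|1/F|⌋−1, ⌊|1/G|⌋−1 (∞ when the field is 0).

    A large vector field gives period 0, i.e. the register shifts on every
    tick; a vanishing field freezes the corresponding variable.
    """
    F, G = eval_vector_field(state, params)
    return _period(F), _period(G)


def eval_directions(state: ACANState, params: ACANParams) -> tuple[int, int]:
    """Shift directions (δV, δU) = (sgn F, sgn G) with sgn(0) = 0."""
    F, G = eval_vector_field(state, params)
    return int(np.sign(F)), int(np.sign(G))


def eval_reset(state: ACANState, params: ACANParams) -> tuple[int, int]:
    """Post-spike reset targets (A, B) for (V, U).

    B is clipped into the recovery register; presets with negative ρ2 would
    otherwise leave it.
    """
    A, Boff = params.reset_values
    B = min(max(state.U + Boff, 0), params.M - 1)
    return A, B


def control_signals(state: ACANState, params: ACANParams) -> ControlSignals:
    """The (sV, sU, δV, δU) signals the vector-field unit asserts this tick."""
    Ph, Qh = eval_periods(state, params)
    dV, dU = eval_directions(state, params)
    return ControlSignals(
        sV=int(state.P >= Ph), sU=int(state.Q >= Qh), deltaV=dV, deltaU=dU
    )


def tick(state: ACANState, params: ACANParams) -> tuple[ACANState, int]:
    """Advance one internal clock tick; returns (new state, fired flag).

    Order within a tick: the velocity counters increment (saturating at
    their register ceiling); each counter that has reached its period shifts
    its variable one place in the direction of the vector field (saturating
    at the register ends) and resets to zero; finally, if V sits at the
    membrane ceiling N−1 a spike is emitted and the state resets to (A, B).
    """
    p = params
    P = min(state.P + 1, p.K - 1)
    Q = min(state.Q + 1, p.J - 1)
    pre = ACANState(state.V, state.U, P, Q)
    Ph, Qh = eval_periods(pre, p)
    dV, dU = eval_directions(pre, p)
    V, U = state.V, state.U
    if Ph != INFINITE and P >= Ph:
        P = 0
        V = min(max(V + dV, 0), p.N - 1)
    if Qh != INFINITE and Q >= Qh:
        Q = 0
        U = min(max(U + dU, 0), p.M - 1)
    fired = 0
    if V >= p.N - 1:
        fired = 1
        A, Boff = p.reset_values
        V = A
        U = min(max(U + Boff, 0), p.M - 1)
    return ACANState(V, U, P, Q), fired


def default_initial_state(params: ACANParams) -> ACANState:
    """Rest-like start: membrane at the reset value A, everything else zero."""
    A, _ = params.reset_values
    return ACANState(V=A, U=0, P=0, Q=0)


def apply_stimulus(state: ACANState, stim: float, params: ACANParams) -> ACANState:
    """Additive stimulus coupling: V ← clip(V + round(stim), 0, N−1).

    The weighted input is rounded to register units; negative stimulus
    (inhibition) is allowed and is required by the inhibition-driven preset
    types.
    """
    kick = int(np.rint(stim))
    V = min(max(state.V + kick, 0), params.N - 1)
    return ACANState(V, state.U, state.P, state.Q)


def simulate(
    params: ACANParams,
    stimulus: Sequence[float] | np.ndarray,
    initial_state: Optional[ACANState] = None,
) -> NeuronTrace:
    """Simulate one neuron over an external stimulus series.

    Each external time step applies the stimulus kick to V, then runs
    ``params.ticks_per_step`` internal ticks.  V is recorded at the end of
    each step; Y flags steps during which the neuron fired.  The result is
    fully deterministic given (params, stimulus, initial_state).
    """
    stim = np.asarray(stimulus, dtype=np.float64)
    if stim.ndim != 1:
        raise ValueError("stimulus must be one-dimensional")
    if not np.all(np.isfinite(stim)):
        raise ValueError("stimulus must be finite")
    s0 = initial_state if initial_state is not None else default_initial_state(params)
    s0.validate(params)
    p = params
    V_trace, Y, V, U, P, Q = simulate_kernel(
        stim,
        p.gamma1, p.gamma2, p.gamma3, p.gamma4, p.gamma5,
        p.lam, p.mu, p.rho1, p.rho2,
        p.N, p.M, p.K, p.J, p.ticks_per_step,
        s0.V, s0.U, s0.P, s0.Q,
    )
    return NeuronTrace(V_trace=V_trace, Y=Y, final_state=ACANState(int(V), int(U), int(P), int(Q)))


def simulate_reference(
    params: ACANParams,
    stimulus: Sequence[float] | np.ndarray,
    initial_state: Optional[ACANState] = None,
) -> NeuronTrace:
    """Pure-Python simulation used to pin down the tick semantics.

    Slow; exists so the compiled kernel can be checked against the
    :func:`tick` definition bit for bit.
    """
    stim = np.asarray(stimulus, dtype=np.float64)
    state = initial_state if initial_state is not None else default_initial_state(params)
    state.validate(params)
    V_trace = np.empty(len(stim), dtype=np.int64)
    Y = np.zeros(len(stim), dtype=np.int64)
    for t, s in enumerate(stim):
        state = apply_stimulus(state, s, params)
        fired_any = 0
        for _ in range(params.ticks_per_step):
            state, fired = tick(state, params)
            fired_any |= fired
        V_trace[t] = state.V
        Y[t] = fired_any
    return NeuronTrace(V_trace=V_trace, Y=Y, final_state=state)
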