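"""Compiled inner loops for ACAN simulation.

The tick-level update is a tight integer loop (four registers, one vector
field evaluation per tick), so it is JIT-compiled with numba.  The pure
Python reference implementation in :mod:`acanet.neuron` (`tick`) defines the
semantics; the kernels here must agree with it bit for bit, which the test
suite checks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_kernel", "simulate_bank_kernel"]


@njit(cache=True)
def _one_step(
    V, U, P, Q, stim,
    g1, g2, g3, g4, g5, lam, mu, rho1, rho2,
    N, M, K, J, ticks,
):
    """Advance one external time step; returns (V, U, P, Q, fired)."""
    # stimulus coupling: additive kick in register units, saturating
    kick = int(np.rint(stim))
    V = V + kick
    if V < 0:
        V = 0
    elif V > N - 1:
        V = N - 1
    fired = 0
    A = int(np.floor(rho1 * N))
    Boff = int(np.floor(rho2 * M))
    for _ in range(ticks):
        # counters advance, saturating at the register ceiling
        if P < K - 1:
            P += 1
        if Q < J - 1:
            Q += 1
        # vector field at the pre-shift state
        F = N * (g1 * (V / N - g2) ** 2 + g3 - U / M) / lam
        G = mu * M * (g4 * (V / N - g2) + (g3 + g5) - U / M) / lam
        # membrane shift
        if F != 0.0:
            ph = np.floor(np.abs(1.0 / F)) - 1.0
            if ph < 0.0:
                ph = 0.0
            if P >= ph:
                P = 0
                if F > 0.0:
                    if V < N - 1:
                        V += 1
                elif V > 0:
                    V -= 1
        # recovery shift
        if G != 0.0:
            qh = np.floor(np.abs(1.0 / G)) - 1.0
            if qh < 0.0:
                qh = 0.0
            if Q >= qh:
                Q = 0
                if G > 0.0:
                    if U < M - 1:
                        U += 1
                elif U > 0:
                    U -= 1
        # firing: membrane register ceiling reached -> reset to (A, B)
        if V >= N - 1:
            fired = 1
            V = A
            B = U + Boff
            if B < 0:
                B = 0
            elif B > M - 1:
                B = M - 1
            U = B
    return V, U, P, Q, fired


@njit(cache=True)
def simulate_kernel(
    stimulus,
    g1, g2, g3, g4, g5, lam, mu, rho1, rho2,
    N, M, K, J, ticks,
    V0, U0, P0, Q0,
):
    """Simulate one neuron over `len(stimulus)` external steps.

    Returns (V_trace, Y) as int64 arrays; V is recorded at the end of each
    step and Y flags steps during which at least one tick fired.
    """
    T = stimulus.shape[0]
    V_trace = np.empty(T, dtype=np.int64)
    Y = np.zeros(T, dtype=np.int64)
    V, U, P, Q = V0, U0, P0, Q0
    for t in range(T):
        V, U, P, Q, fired = _one_step(
            V, U, P, Q, stimulus[t],
            g1, g2, g3, g4, g5, lam, mu, rho1, rho2,
            N, M, K, J, ticks,
        )
        V_trace[t] = V
        Y[t] = fired
    return V_trace, Y, V, U, P, Q


@njit(cache=True)
def simulate_bank_kernel(
    stimuli,
    g1, g2, g3, g4, g5, lam, mu, rho1, rho2,
    N, M, K, J, ticks,
    V0, U0, P0, Q0,
):
    """Simulate a bank of identical neurons, one row of `stimuli` each.

    All neurons start from the same initial state; returns the
    (n_neurons, T) binary output spike matrix.
    """
    n, T = stimuli.shape
    Y = np.zeros((n, T), dtype=np.int64)
    for i in range(n):
        V, U, P, Q = V0, U0, P0, Q0
        for t in range(T):
            V, U, P, Q, fired = _one_step(
                V, U, P, Q, stimuli[i, t],
                g1, g2, g3, g4, g5, lam, mu, rho1, rho2,
                N, M, K, J, ticks,
            )
            Y[i, t] = fired
    return Y
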