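"""Unit tests of the ACAN register dynamics and behaviour presets."""

import math

import numpy as np
import pytest

from acanet.neuron import (
    ACANParams,
    ACANState,
    INFINITE,
    PRESET_LABELS,
    control_signals,
    eval_directions,
    eval_periods,
    eval_reset,
    eval_vector_field,
    preset_params,
    simulate,
    simulate_reference,
    tick,
)
from conftest import random_params


class TestPresets:
    def test_type_a_row(self):
        p = preset_params("a", 64)
        assert (p.gamma1, p.gamma2, p.gamma3, p.gamma4, p.gamma5) == (7, 0.3, 0.2, 2.8, 0.06)
        assert (p.lam, p.mu, p.rho1, p.rho2) == (64, 0.7, 0.3, 0)
        assert (p.N, p.M, p.K, p.J) == (64, 64, 64, 64)

    def test_type_t_row(self):
        p = preset_params("t", 128)
        assert (p.gamma1, p.gamma2, p.gamma3, p.gamma4, p.gamma5) == (7, 0.3, 0.5, -5, 0)
        assert (p.lam, p.mu, p.rho1, p.rho2) == (128, -0.1, 0.55, -0.1)

    def test_unknown_label_names_valid_ones(self):
        with pytest.raises(KeyError, match="a, b, c"):
            preset_params("z", 64)

    def test_all_twenty_labels_instantiate(self):
        for lbl in PRESET_LABELS:
            p = preset_params(lbl, 32)
            assert p.N == p.M == p.K == p.J == 32

    def test_phasic_config_shares_tonic_parameters(self):
        # the spiking-vs-phasic distinction of rows a and b lies in the
        # stimulus protocol, not the parameter vector
        assert preset_params("a", 64) == preset_params("b", 64)


class TestVectorField:
    def test_type_a_at_origin(self, type_a_64):
        F, G = eval_vector_field(ACANState(V=0, U=0), type_a_64)
        assert F == pytest.approx(7 * 0.09 + 0.2)  # 0.83
        assert G == pytest.approx(0.7 * (2.8 * (-0.3) + 0.26))  # -0.406

    def test_nullcline_zeroes_f(self):
        # U/M equal to gamma1 (V/N - gamma2)^2 + gamma3 makes the numerator vanish
        p = ACANParams(
            gamma1=2.0, gamma2=0.5, gamma3=0.25, gamma4=1.0, gamma5=0.0,
            lam=4.0, mu=1.0, rho1=0.3, rho2=0.0, N=4, M=4, K=4, J=4,
        )
        # V=2 -> V/N - g2 = 0 -> need U/M = 0.25 -> U = 1
        F, _ = eval_vector_field(ACANState(V=2, U=1), p)
        assert F == 0.0

    def test_periods_from_field_values(self, type_a_64):
        Ph, Qh = eval_periods(ACANState(V=0, U=0), type_a_64)
        # F = 0.83 -> floor(1.2048) - 1 = 0; G = -0.406 -> floor(2.463) - 1 = 1
        assert Ph == 0
        assert Qh == 1

    def test_zero_field_gives_infinite_period(self):
        p = ACANParams(
            gamma1=0.0, gamma2=0.0, gamma3=0.5, gamma4=0.0, gamma5=0.0,
            lam=8.0, mu=0.0, rho1=0.0, rho2=0.0, N=8, M=8, K=8, J=8,
        )
        Ph, Qh = eval_periods(ACANState(V=0, U=4), p)  # U/M = 0.5 = gamma3
        assert Ph == INFINITE and Qh == INFINITE

    def test_small_field_gives_long_period(self):
        # |F| = 0.1 -> floor(10) - 1 = 9
        p = ACANParams(
            gamma1=0.0, gamma2=0.0, gamma3=0.1, gamma4=0.0, gamma5=0.0,
            lam=1.0, mu=1.0, rho1=0.0, rho2=0.0, N=2, M=2, K=2, J=2,
        )
        # F = N * gamma3 / lam with U=0 -> 0.2 ... construct directly instead:
        F, _ = eval_vector_field(ACANState(V=0, U=0), p)
        assert F == pytest.approx(0.2)
        Ph, _ = eval_periods(ACANState(V=0, U=0), p)
        assert Ph == math.floor(1 / 0.2) - 1 == 4

    def test_directions_follow_signs(self, type_a_64):
        assert eval_directions(ACANState(V=0, U=0), type_a_64) == (1, -1)

    def test_direction_zero_on_zero_field(self):
        p = ACANParams(
            gamma1=0.0, gamma2=0.0, gamma3=0.5, gamma4=0.0, gamma5=0.0,
            lam=8.0, mu=0.0, rho1=0.0, rho2=0.0, N=8, M=8, K=8, J=8,
        )
        assert eval_directions(ACANState(V=0, U=4), p) == (0, 0)


class TestReset:
    def test_reset_membrane_floor(self, type_a_64):
        A, B = eval_reset(ACANState(V=0, U=10), type_a_64)
        assert A == 19  # floor(0.3 * 64)
        assert B == 10  # rho2 = 0 keeps U

    def test_reset_negative_offset_clips(self):
        p = preset_params("a", 64).with_(rho2=-0.2)
        _, B = eval_reset(ACANState(V=0, U=5), p)
        assert B == 0  # 5 + floor(-12.8) = -8 -> clipped


class TestTick:
    def test_frozen_dynamics_only_counters_move(self):
        p = ACANParams(
            gamma1=0.0, gamma2=0.0, gamma3=0.5, gamma4=0.0, gamma5=0.0,
            lam=8.0, mu=0.0, rho1=0.0, rho2=0.0, N=8, M=8, K=8, J=8,
        )
        s = ACANState(V=3, U=4, P=1, Q=2)  # F = G = 0 here
        s2, fired = tick(s, p)
        assert fired == 0
        assert (s2.V, s2.U) == (3, 4)
        assert (s2.P, s2.Q) == (2, 3)

    def test_ceiling_triggers_reset(self, type_a_64):
        p = type_a_64.with_(mu=0.0)  # freeze U so the reset value is unambiguous
        s = ACANState(V=63, U=10, P=0, Q=0)
        s2, fired = tick(s, p)
        assert fired == 1
        assert s2.V == 19  # A = floor(0.3*64)
        assert s2.U == 10  # rho2 = 0

    def test_shift_direction_matches_field_sign(self, rng):
        # oracle: re-evaluate the control signals at the post-increment,
        # pre-shift state and check the applied shift agrees
        for _ in range(300):
            p = random_params(rng)
            s = ACANState(
                V=int(rng.integers(0, p.N)), U=int(rng.integers(0, p.M)),
                P=int(rng.integers(0, p.K)), Q=int(rng.integers(0, p.J)),
            )
            pre = ACANState(s.V, s.U, min(s.P + 1, p.K - 1), min(s.Q + 1, p.J - 1))
            sig = control_signals(pre, p)
            s2, fired = tick(s, p)
            if not fired and sig.sV:
                expected = min(max(s.V + sig.deltaV, 0), p.N - 1)
                assert s2.V == expected

    def test_register_bounds_fuzz(self, rng):
        for _ in range(200):
            p = random_params(rng)
            s = ACANState(
                V=int(rng.integers(0, p.N)), U=int(rng.integers(0, p.M)),
                P=int(rng.integers(0, p.K)), Q=int(rng.integers(0, p.J)),
            )
            for _ in range(50):
                s, _ = tick(s, p)
                s.validate(p)


class TestSimulate:
    def test_flat_at_fixed_point(self):
        p = ACANParams(
            gamma1=0.0, gamma2=0.0, gamma3=0.5, gamma4=0.0, gamma5=0.0,
            lam=8.0, mu=0.0, rho1=0.0, rho2=0.0, N=8, M=8, K=8, J=8,
        )
        tr = simulate(p, np.zeros(50), ACANState(V=3, U=4))
        assert np.all(tr.V_trace == 3)
        assert tr.spike_count == 0

    def test_deterministic_bit_for_bit(self, type_a_64, rng):
        stim = rng.normal(0, 10, 100)
        t1 = simulate(type_a_64, stim)
        t2 = simulate(type_a_64, stim)
        assert np.array_equal(t1.V_trace, t2.V_trace)
        assert np.array_equal(t1.Y, t2.Y)
        assert t1.final_state == t2.final_state

    def test_kernel_matches_python_reference(self, rng):
        for _ in range(5):
            p = random_params(rng)
            p = p.with_(ticks_per_step=min(p.ticks_per_step, 8))
            stim = rng.normal(0, p.N / 4, 40)
            fast = simulate(p, stim)
            slow = simulate_reference(p, stim)
            assert np.array_equal(fast.V_trace, slow.V_trace)
            assert np.array_equal(fast.Y, slow.Y)
            assert fast.final_state == slow.final_state

    def test_tonic_preset_fires_under_sustained_drive(self, type_a_64):
        settle = simulate(type_a_64, np.zeros(100))
        tr = simulate(type_a_64, np.full(200, 15.0), settle.final_state)
        assert tr.spike_count >= 3

    def test_inhibition_induced_preset_fires_under_negative_drive(self):
        p = preset_params("s", 64)
        settle = simulate(p, np.zeros(100))
        inh = simulate(p, np.full(200, -4.0), settle.final_state)
        rest = simulate(p, np.zeros(200), settle.final_state)
        assert inh.spike_count >= 1
        assert rest.spike_count == 0

    def test_invalid_inputs_rejected(self, type_a_64):
        with pytest.raises(ValueError):
            simulate(type_a_64, np.array([np.nan, 0.0]))
        with pytest.raises(ValueError):
            simulate(type_a_64, np.zeros(5), ACANState(V=99, U=0))


class TestParamValidation:
    def test_register_size_floor(self):
        with pytest.raises(ValueError):
            preset_params("a", 1)

    def test_rho1_must_keep_reset_inside_register(self):
        with pytest.raises(ValueError):
            preset_params("a", 64).with_(rho1=1.0)
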