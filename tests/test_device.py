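"""Memristor behavioral model: transfer curve, STDP rule, PWM writes."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memcpg.device import (
    DEFAULT_ANCHORS,
    MemristorState,
    STDPParams,
    TransferCalibration,
    apply_pwm_update,
    apply_write_voltage,
    pair_nearest,
    stdp_learning_signal,
    transfer_amplitude,
)


class TestTransferCalibration:
    @pytest.mark.parametrize("resistance, amplitude", [(170.0, 0.4), (60.0, 0.85), (30.0, 1.6)])
    def test_anchor_amplitudes_reproduced_exactly(self, resistance, amplitude):
        cal = TransferCalibration()
        assert transfer_amplitude(cal, resistance) == pytest.approx(amplitude, abs=1e-12)

    def test_low_resistance_extrapolation_is_linear_in_conductance(self):
        # independent oracle: A = a + b/R through the two lowest anchors
        (r0, a0), (r1, a1) = DEFAULT_ANCHORS[0], DEFAULT_ANCHORS[1]
        b = (a0 - a1) / (1.0 / r0 - 1.0 / r1)
        a = a0 - b / r0
        cal = TransferCalibration()
        assert (a, b) == pytest.approx((0.1, 45.0))
        assert transfer_amplitude(cal, 20.0) == pytest.approx(a + b / 20.0)
        assert transfer_amplitude(cal, 20.0) == pytest.approx(2.35)

    def test_strictly_monotone_decreasing_over_device_range(self):
        cal = TransferCalibration()
        grid = np.linspace(20.0, 200.0, 1801)
        amps = np.array([cal.evaluate(r) for r in grid])
        assert np.all(np.diff(amps) < 0)
        assert np.all(amps >= 0)

    def test_out_of_bounds_resistance_rejected(self):
        cal = TransferCalibration()
        with pytest.raises(ValueError):
            transfer_amplitude(cal, 10.0)
        with pytest.raises(ValueError):
            transfer_amplitude(cal, 250.0)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            TransferCalibration(((30.0, 1.0), (60.0, 1.5)))


class TestSTDP:
    def test_shape_of_learning_function(self):
        p = STDPParams(a_plus=1e-3, a_minus=5e-4)
        assert stdp_learning_signal(p, p.window + 1.0) == 0.0
        assert stdp_learning_signal(p, -p.window - 1.0) == 0.0
        # boundary of the exponential: maximal potentiation as dt -> 0+
        assert stdp_learning_signal(p, 1e-9) == pytest.approx(p.a_plus)
        # closed-form decay at one time constant
        assert stdp_learning_signal(p, p.tau_plus) == pytest.approx(p.a_plus / math.e)
        assert stdp_learning_signal(p, -p.tau_minus) == pytest.approx(-p.a_minus / math.e)

    @given(delta_t=st.floats(-100.0, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sign_follows_causality(self, delta_t):
        p = STDPParams(a_plus=1e-3, a_minus=5e-4)
        s = stdp_learning_signal(p, delta_t)
        if 0 < delta_t <= p.window:
            assert s > 0
        elif -p.window <= delta_t < 0:
            assert s < 0
        else:
            assert s == 0.0


class TestPWMUpdate:
    def test_zero_magnitude_is_identity(self):
        state = MemristorState(100.0)
        assert apply_pwm_update(state, STDPParams(), 0.0) == state

    def test_conductance_arithmetic(self):
        # oracle: G' = 1/40 + 0.005 -> R' = 1/G'
        state = MemristorState(40.0)
        out = apply_pwm_update(state, STDPParams(pwm_gain=1.0), 5e-3)
        assert out.resistance == pytest.approx(1.0 / (1.0 / 40.0 + 5e-3))
        assert out.resistance == pytest.approx(33.3333, abs=1e-3)

    def test_clipping_at_floor(self):
        state = MemristorState(20.0)
        assert apply_pwm_update(state, STDPParams(), 1.0).resistance == 20.0

    @given(st.lists(st.floats(-0.02, 0.02), max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_resistance_never_leaves_device_bounds(self, magnitudes):
        state = MemristorState(100.0)
        params = STDPParams()
        for m in magnitudes:
            state = apply_pwm_update(state, params, m)
            assert state.r_min <= state.resistance <= state.r_max

    def test_repeated_potentiation_and_depression_fixed_points(self):
        params = STDPParams()
        state = MemristorState(100.0)
        for _ in range(200):
            state = apply_pwm_update(state, params, 1e-3)
        assert state.resistance == state.r_min
        for _ in range(200):
            state = apply_pwm_update(state, params, -1e-3)
        assert state.resistance == state.r_max


class TestWriteVoltageGates:
    def test_read_window_leaves_state_untouched(self):
        state = MemristorState(100.0)
        assert apply_write_voltage(state, 0.3) == state

    def test_set_and_reset_move_resistance_oppositely(self):
        state = MemristorState(100.0)
        assert apply_write_voltage(state, 1.0).resistance < 100.0
        assert apply_write_voltage(state, -0.5).resistance > 100.0


class TestPairing:
    def test_empty_sides_give_no_pairs(self):
        assert pair_nearest([], [10.0]) == []
        assert pair_nearest([10.0], []) == []

    def test_each_pre_pairs_with_nearest_post(self):
        pairs = pair_nearest([100.0, 110.0], [102.0, 130.0])
        assert pairs == [(100.0, 102.0, 2.0), (110.0, 102.0, -8.0)]

    def test_ties_break_causally(self):
        (_, t_post, dt), = pair_nearest([100.0], [95.0, 105.0])
        assert (t_post, dt) == (105.0, 5.0)


def test_memristor_state_bounds_enforced():
    with pytest.raises(ValueError):
        MemristorState(10.0)
    with pytest.raises(ValueError):
        MemristorState(100.0, r_min=-1.0)
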