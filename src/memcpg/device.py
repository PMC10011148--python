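"""Behavioral model of the organic (PANI) memristive synapse.

The memristor enters the circuit in two roles:

* **read path** — the 200 Hz sensory train passes through the "memristive
  integration block", which scales the pulse amplitude as a decreasing
  function of the device resistance (high resistance -> small pulses).
  :func:`transfer_amplitude` models that mapping, calibrated on measured
  anchor pairs (30 kOhm -> 1.6 V, 60 kOhm -> 0.85 V, 170 kOhm -> 0.4 V),
  with monotone shape-preserving (PCHIP) interpolation between anchors and
  a voltage-divider-like linear-in-1/R extrapolation outside their span.

* **write path** — after each trial a learning-feedback stage compares the
  rising edges of the 200 Hz pre-synaptic pulses with the neuron's output
  spikes and converts each pairing interval dt = t_post - t_pre into a
  signed learning magnitude (:func:`stdp_learning_signal`, exponential
  pair-based STDP).  A PWM write stage, abstracted here to a scalar gain,
  turns the summed magnitude into a conductance step
  (:func:`apply_pwm_update`), clipped to the device's resistance range.

The device's sharp voltage-threshold switching (set/reset gates) is kept
as an optional characterisation routine (:func:`apply_write_voltage`); the
learning loop always writes through the PWM path.  No electrochemical
kinetics, hysteresis curves or endurance effects are modelled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "MemristorState",
    "TransferCalibration",
    "STDPParams",
    "transfer_amplitude",
    "stdp_learning_signal",
    "apply_pwm_update",
    "apply_write_voltage",
    "pair_nearest",
    "DEFAULT_ANCHORS",
    "R_MIN_DEFAULT",
    "R_MAX_DEFAULT",
]

#: Measured (resistance kOhm, 200 Hz output amplitude V) anchor pairs.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (30.0, 1.6),
    (60.0, 0.85),
    (170.0, 0.4),
)

#: Device resistance range (kOhm).  Learning runs terminate at the 20 kOhm
#: floor; the largest initial state used is 170 kOhm.
R_MIN_DEFAULT = 20.0
R_MAX_DEFAULT = 200.0


@dataclass(frozen=True)
class MemristorState:
    """Bounded device resistance plus its write-threshold gates.

    ``v_set``/``v_reset`` are the voltages above/below which a directly
    applied write pulse switches the device; they are not printed for this
    device batch and are plain configuration parameters.
    """

    resistance: float
    r_min: float = R_MIN_DEFAULT
    r_max: float = R_MAX_DEFAULT
    v_set: float = 0.8
    v_reset: float = -0.2

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise ValueError(f"r_min must be > 0, got {self.r_min}")
        if self.r_min > self.r_max:
            raise ValueError(f"r_min {self.r_min} > r_max {self.r_max}")
        if not (self.r_min <= self.resistance <= self.r_max):
            raise ValueError(
                f"resistance {self.resistance} kOhm outside device bounds "
                f"[{self.r_min}, {self.r_max}]"
            )

    @property
    def conductance(self) -> float:
        """Conductance in 1/kOhm."""
        return 1.0 / self.resistance


@dataclass(frozen=True)
class TransferCalibration:
    """Resistance -> 200 Hz output amplitude mapping of the read path.

    Exact at the anchors, strictly decreasing in R everywhere, clamped to
    non-negative amplitudes.  ``evaluate`` performs no bounds check (used
    by the fixed-resistor control path); :func:`transfer_amplitude`
    enforces the device bounds.
    """

    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        anchors = tuple(sorted((float(r), float(a)) for r, a in self.anchors))
        if len(anchors) < 2:
            raise ValueError("need at least two calibration anchors")
        rs = [r for r, _ in anchors]
        amps = [a for _, a in anchors]
        if rs[0] <= 0:
            raise ValueError("anchor resistances must be positive")
        if any(b >= a for a, b in zip(amps, amps[1:])):
            raise ValueError("anchor amplitudes must strictly decrease with R")
        object.__setattr__(self, "anchors", anchors)

    @cached_property
    def _interp(self) -> PchipInterpolator:
        rs = np.array([r for r, _ in self.anchors])
        amps = np.array([a for _, a in self.anchors])
        return PchipInterpolator(rs, amps, extrapolate=False)

    def _inv_r_line(self, r: float, p0: tuple[float, float], p1: tuple[float, float]) -> float:
        # amplitude linear in conductance through two anchors: A = a + b/R
        (r0, a0), (r1, a1) = p0, p1
        b = (a0 - a1) / (1.0 / r0 - 1.0 / r1)
        a = a0 - b / r0
        return a + b / r

    def evaluate(self, resistance: float) -> float:
        """Amplitude (V) at any positive resistance; no device-bounds check."""
        if resistance <= 0:
            raise ValueError(f"resistance must be > 0, got {resistance}")
        r_lo, _ = self.anchors[0]
        r_hi, _ = self.anchors[-1]
        if resistance < r_lo:
            amp = self._inv_r_line(resistance, self.anchors[0], self.anchors[1])
        elif resistance > r_hi:
            amp = self._inv_r_line(resistance, self.anchors[-2], self.anchors[-1])
        else:
            amp = float(self._interp(resistance))
        return max(0.0, amp)


@dataclass(frozen=True)
class STDPParams:
    """Exponential pair-based STDP plus the PWM write gain.

    ``a_plus``/``a_minus`` are conductance increments (1/kOhm) at zero
    pairing interval, ``tau_plus``/``tau_minus`` decay constants (ms),
    ``window`` the pairing window (ms) beyond which a pair is ignored, and
    ``pwm_gain`` the dimensionless scale from learning magnitude to the
    conductance step written by the PWM stage.  ``a_minus`` defaults to 0:
    the hardware runs reported only monotone resistance decrease.
    """

    a_plus: float = 1.2e-4
    a_minus: float = 0.0
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    window: float = 25.0
    pwm_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.a_plus <= 0:
            raise ValueError(f"a_plus must be > 0, got {self.a_plus}")
        if self.a_minus < 0:
            raise ValueError(f"a_minus must be >= 0, got {self.a_minus}")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be > 0")
        if self.window <= 0:
            raise ValueError(f"pairing window must be > 0, got {self.window}")


def transfer_amplitude(
    cal: TransferCalibration,
    resistance: float,
    r_min: float = R_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
) -> float:
    """200 Hz output amplitude (V) of the integration block at ``resistance``.

    Strictly decreasing in resistance, exact at the calibration anchors.
    Raises if the resistance lies outside the device bounds (the
    fixed-resistor control path uses ``cal.evaluate`` directly).
    """
    if not (r_min <= resistance <= r_max):
        raise ValueError(
            f"resistance {resistance} kOhm outside device bounds [{r_min}, {r_max}]"
        )
    return cal.evaluate(resistance)


def stdp_learning_signal(params: STDPParams, delta_t: float) -> float:
    """Signed learning magnitude for a pre/post pairing interval.

    ``delta_t = t_post - t_pre``.  Causal pairs (``0 < delta_t <= window``)
    potentiate with magnitude ``a_plus * exp(-delta_t/tau_plus)``;
    anti-causal pairs depress with ``-a_minus * exp(delta_t/tau_minus)``;
    pairs outside the window (and exactly coincident edges) contribute 0.
    """
    if 0 < delta_t <= params.window:
        return params.a_plus * math.exp(-delta_t / params.tau_plus)
    if -params.window <= delta_t < 0:
        return -params.a_minus * math.exp(delta_t / params.tau_minus)
    return 0.0


def apply_pwm_update(
    state: MemristorState, params: STDPParams, learning_magnitude: float
) -> MemristorState:
    """Write one PWM-mediated conductance step onto the device.

    The conductance moves by ``pwm_gain * learning_magnitude`` (1/kOhm)
    and is clipped to the device range, so positive magnitudes strictly
    decrease the resistance unless the device already sits at its floor.
    """
    g = state.conductance + params.pwm_gain * learning_magnitude
    g = min(max(g, 1.0 / state.r_max), 1.0 / state.r_min)
    return replace(state, resistance=1.0 / g)


def apply_write_voltage(
    state: MemristorState, voltage: float, g_step: float = 2e-3
) -> MemristorState:
    """Characterisation-only threshold switching by a direct write pulse.

    Voltages at or above ``v_set`` step the conductance up by ``g_step``,
    at or below ``v_reset`` step it down; amplitudes between the gates
    read the device without disturbing it.
    """
    if voltage >= state.v_set:
        delta = g_step
    elif voltage <= state.v_reset:
        delta = -g_step
    else:
        return state
    g = min(max(state.conductance + delta, 1.0 / state.r_max), 1.0 / state.r_min)
    return replace(state, resistance=1.0 / g)


def pair_nearest(
    pre_times: np.ndarray, post_times: np.ndarray
) -> list[tuple[float, float, float]]:
    """Nearest-neighbour pre/post pairing.

    Each pre-synaptic rising edge is paired with the output spike closest
    in time (ties broken toward the causal, later spike).  Returns
    ``(t_pre, t_post, delta_t)`` triples with ``delta_t = t_post - t_pre``;
    empty if either side is empty.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.sort(np.asarray(post_times, dtype=float))
    if pre.size == 0 or post.size == 0:
        return []
    pairs = []
    for t_pre in pre:
        deltas = post - t_pre
        order = np.lexsort((-deltas, np.abs(deltas)))  # closest; tie -> positive
        t_post = float(post[order[0]])
        pairs.append((float(t_pre), t_post, t_post - t_pre))
    return pairs
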