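"""Leaky integrate-and-fire building blocks: adder, leakage integrator, delay.

Every neuron in the circuit is the same three-stage pipeline: an adder sums
its sampled input channels, a leakage integrator turns the sum into a
membrane potential with exponential leak and threshold/reset dynamics, and
a delay block shifts the resulting spikes on their way to the motor neuron
(emulating synaptic conduction delays).

Membrane update on a uniform grid of step ``dt``::

    V[i] = V[i-1] * exp(-dt/tau_m) + u[i-1] * dt/tau_m

so a sustained input of amplitude ``A`` saturates the membrane at ``A``.
When ``V`` reaches the threshold the neuron emits a spike, the potential
drops to ``v_reset`` (< 0) and recovers linearly to 0 V over the
refractory period ``t_ref``, during which all input is ignored ("no pulse
can raise this potential above zero").  Spikes are instantaneous events;
:func:`spikes_to_pulses` rasterizes them into rectangular pulses for
downstream adders.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .device import MemristorState

__all__ = [
    "LIFParams",
    "MembraneTrace",
    "NeuronConfig",
    "adder",
    "integrate_membrane",
    "delay_block",
    "spikes_to_pulses",
]


@dataclass(frozen=True)
class LIFParams:
    """Leakage-integrator constants.

    ``threshold`` (V) and ``tau_m`` (ms) are set by the circuit-level
    calibration against the printed spike-count scenarios; ``v_reset`` and
    ``t_ref`` reproduce the printed sub-zero refractory interval (15 ms).
    ``pulse_amplitude``/``pulse_width`` describe the rectangular output
    pulse a spike injects into downstream adders.
    """

    threshold: float = 0.63
    tau_m: float = 8.0
    v_reset: float = -0.5
    t_ref: float = 15.0
    pulse_amplitude: float = 10.0
    pulse_width: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.v_reset >= 0:
            raise ValueError(f"v_reset must be < 0, got {self.v_reset}")
        if self.t_ref <= 0:
            raise ValueError(f"t_ref must be > 0, got {self.t_ref}")
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if self.pulse_amplitude <= 0 or self.pulse_width <= 0:
            raise ValueError("output pulse amplitude and width must be > 0")


@dataclass
class MembraneTrace:
    """Sampled membrane potential plus the emitted spike times."""

    dt: float
    potential: np.ndarray
    spike_times: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.potential.size) * self.dt

    def check_invariants(self, params: LIFParams) -> None:
        """Assert the trace obeys the integrator contract (test helper)."""
        v = self.potential
        spike_idx = np.rint(self.spike_times / self.dt).astype(int)
        non_spike = np.ones(v.size, dtype=bool)
        non_spike[spike_idx] = False
        if np.any(v[non_spike] >= params.threshold):
            raise AssertionError("potential reached threshold outside a spike")
        ref_steps = int(round(params.t_ref / self.dt))
        for s in spike_idx:
            if not np.isclose(v[s], params.v_reset):
                raise AssertionError("potential not reset to v_reset at spike")
            seg = v[s : min(s + ref_steps, v.size)]
            if np.any(seg >= 0):
                raise AssertionError("potential not sub-zero through refractory")


@dataclass(frozen=True)
class NeuronConfig:
    """Wiring of one neuron: kind, input channels, weight, and MN delay.

    ``kind`` is ``"LN"`` (fixed-resistor input weight), ``"MemN"``
    (memristive weight) or ``"MN"`` (motor neuron: no sensory weight, it
    receives the delayed spikes of the four pattern neurons plus the EES
    train).  ``weight`` is a fixed resistance in kOhm for LNs, a
    :class:`~memcpg.device.MemristorState` for MemNs and ``None`` for the
    MN.
    """

    name: str
    kind: str
    channels: tuple[str, ...]
    lif: LIFParams
    weight: float | MemristorState | None = None
    delay_to_mn: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("LN", "MemN", "MN"):
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if self.kind == "MemN" and not isinstance(self.weight, MemristorState):
            raise ValueError(f"{self.name}: MemN requires a MemristorState weight")
        if self.kind == "LN" and not isinstance(self.weight, (int, float)):
            raise ValueError(f"{self.name}: LN requires a fixed resistance weight")
        if self.kind == "MN" and self.weight is not None:
            raise ValueError("MN carries no input weight")
        if self.delay_to_mn < 0:
            raise ValueError(f"delay_to_mn must be >= 0, got {self.delay_to_mn}")


def adder(inputs: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise sum of equally sampled voltage sequences."""
    if not inputs:
        raise ValueError("adder needs at least one input")
    arrays = [np.asarray(x, dtype=float) for x in inputs]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError(
            f"adder inputs must share one grid, got lengths {[a.size for a in arrays]}"
        )
    return np.sum(arrays, axis=0)


def integrate_membrane(
    inp: np.ndarray, params: LIFParams, dt: float
) -> MembraneTrace:
    """Run the leakage integrator over one trial.

    ``inp[i]`` is the summed input voltage on ``[i*dt, (i+1)*dt)``.  The
    returned trace has the same grid; spikes are recorded at the grid time
    of the threshold crossing.  During the refractory period the potential
    ramps linearly from ``v_reset`` back to 0 and input is discarded.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    u = np.asarray(inp, dtype=float)
    n = u.size
    v = np.zeros(n)
    spikes: list[float] = []
    decay = float(np.exp(-dt / params.tau_m))
    gain = dt / params.tau_m
    ref_steps = int(round(params.t_ref / dt))
    theta = params.threshold
    v_reset = params.v_reset
    i = 1
    while i < n:
        x = v[i - 1] * decay + u[i - 1] * gain
        if x >= theta:
            spikes.append(i * dt)
            v[i] = v_reset
            stop = min(i + ref_steps, n - 1)
            for j in range(i + 1, stop + 1):
                v[j] = v_reset * (1.0 - (j - i) / ref_steps)
            i = i + ref_steps + 1
        else:
            v[i] = x
            i += 1
    return MembraneTrace(dt=dt, potential=v, spike_times=np.array(spikes))


def delay_block(spike_times: np.ndarray, delay: float) -> np.ndarray:
    """Shift every spike by ``delay`` ms (order preserved)."""
    if delay < 0:
        raise ValueError(f"delay must be >= 0, got {delay}")
    return np.asarray(spike_times, dtype=float) + delay


def spikes_to_pulses(
    spike_times: np.ndarray,
    amplitude: float,
    width: float,
    dt: float,
    trial_length: float,
) -> np.ndarray:
    """Rasterize spike events into rectangular pulses on the trial grid.

    Spikes at or beyond the trial end are dropped (their pulse would fall
    outside the recorded window).
    """
    n = int(round(trial_length / dt))
    out = np.zeros(n)
    for t in np.asarray(spike_times, dtype=float):
        i0 = int(round(t / dt))
        if i0 >= n:
            continue
        i1 = min(int(round((t + width) / dt)), n)
        out[i0:i1] += amplitude
    return out
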