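"""Deterministic pulse-train stimuli for the five-neuron CPG circuit.

Three kinds of rectangular pulse trains drive the circuit over one 250 ms
gait-cycle trial:

* a 20 Hz train shared by every neuron, emulating epidural electrical
  stimulation (EES);
* per-neuron 200 Hz trains gated to staggered 100 ms windows, emulating
  plantar sensory afferents sweeping from heel to toe (blue 0-100 ms,
  yellow 50-150 ms, pink 100-200 ms, green 150-250 ms);
* 100 Hz bootstrap trains on the two plastic (memristive) neurons
  (pink 100-200 ms, green 150-250 ms), used to kick-start learning while
  the memristor is still in its high-resistance, non-conducting state.

All windows are half-open ``[start, end)``: a pulse falling exactly on the
window end is excluded, so a 200 Hz window holds exactly 20 pulses and one
trial holds exactly 5 EES pulses.  Time is 0-based and measured in ms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "PulseTrain",
    "StimulusProtocol",
    "generate_pulse_train",
    "build_default_protocol",
    "rasterize",
    "detect_onsets",
    "PATTERN_NEURONS",
    "MEMRISTIVE_NEURONS",
    "MOTOR_NEURON",
    "SENSORY_WINDOWS_MS",
    "BOOTSTRAP_WINDOWS_MS",
]

PATTERN_NEURONS = ("blue", "yellow", "pink", "green")
MEMRISTIVE_NEURONS = ("pink", "green")
MOTOR_NEURON = "mn"

DEFAULT_TRIAL_MS = 250.0
DEFAULT_DT_MS = 0.1
DEFAULT_PULSE_WIDTH_MS = 1.0

EES_FREQUENCY_HZ = 20.0
SENSORY_FREQUENCY_HZ = 200.0
BOOTSTRAP_FREQUENCY_HZ = 100.0

#: Gating windows (ms) of the 200 Hz sensory trains, heel to toe.
SENSORY_WINDOWS_MS: Mapping[str, tuple[float, float]] = {
    "blue": (0.0, 100.0),
    "yellow": (50.0, 150.0),
    "pink": (100.0, 200.0),
    "green": (150.0, 250.0),
}

#: Gating windows (ms) of the 100 Hz bootstrap trains (plastic neurons only).
BOOTSTRAP_WINDOWS_MS: Mapping[str, tuple[float, float]] = {
    "pink": (100.0, 200.0),
    "green": (150.0, 250.0),
}

_EPS = 1e-9


@dataclass(frozen=True)
class PulseTrain:
    """A train of rectangular pulses with common width and amplitude.

    ``onset_times`` are the rising edges in ms, strictly increasing;
    ``width`` is the pulse width in ms and ``amplitude`` the pulse height
    in volts.  ``label`` names the channel (e.g. ``"green/sensory"``).
    """

    onset_times: tuple[float, ...]
    width: float
    amplitude: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"pulse width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        onsets = tuple(float(t) for t in self.onset_times)
        if any(b - a <= 0 for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onset_times must be strictly increasing")
        if onsets and onsets[0] < 0:
            raise ValueError("onset_times must be non-negative")
        object.__setattr__(self, "onset_times", onsets)

    @property
    def n_pulses(self) -> int:
        return len(self.onset_times)


@dataclass(frozen=True)
class StimulusProtocol:
    """Per-neuron stimulation channels for one trial.

    ``channels`` maps each of the five neurons (blue, yellow, pink, green,
    mn) to its channel dict.  Every neuron carries the shared ``"ees"``
    train; the four pattern neurons carry a ``"sensory"`` 200 Hz train; the
    two memristive neurons additionally carry a ``"bootstrap"`` 100 Hz
    train.
    """

    trial_length: float
    channels: Mapping[str, Mapping[str, PulseTrain]]

    def __post_init__(self) -> None:
        expected = set(PATTERN_NEURONS) | {MOTOR_NEURON}
        if set(self.channels) != expected:
            raise ValueError(
                f"protocol must define exactly the neurons {sorted(expected)}, "
                f"got {sorted(self.channels)}"
            )
        ees_trains = [self.channels[n].get("ees") for n in self.channels]
        if any(t is None for t in ees_trains):
            raise ValueError("every neuron must carry the shared 'ees' channel")
        ref = ees_trains[0]
        for t in ees_trains[1:]:
            if (
                t.onset_times != ref.onset_times
                or t.width != ref.width
                or t.amplitude != ref.amplitude
            ):
                raise ValueError("the 20 Hz EES train must be identical across neurons")
        for name, chans in self.channels.items():
            if ("bootstrap" in chans) != (name in MEMRISTIVE_NEURONS):
                raise ValueError(
                    f"bootstrap channel allowed only on {MEMRISTIVE_NEURONS}, "
                    f"violated by {name!r}"
                )
            for train in chans.values():
                if train.onset_times and train.onset_times[-1] >= self.trial_length:
                    raise ValueError(f"{name}: pulse onsets beyond trial end")

    @property
    def ees(self) -> PulseTrain:
        return self.channels[MOTOR_NEURON]["ees"]


def generate_pulse_train(
    frequency: float,
    window: tuple[float, float],
    amplitude: float,
    width: float = DEFAULT_PULSE_WIDTH_MS,
    trial_length: float = DEFAULT_TRIAL_MS,
    label: str = "",
) -> PulseTrain:
    """Periodic pulse onsets at ``frequency`` Hz inside the half-open window.

    Pulses sit at ``start, start + 1000/frequency, ...`` strictly below
    ``end``.  The window must lie inside ``[0, trial_length]``.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0 Hz, got {frequency}")
    start, end = window
    if not (0 <= start < end <= trial_length):
        raise ValueError(
            f"window [{start}, {end}) must lie within the trial [0, {trial_length})"
        )
    period = 1000.0 / frequency
    count = int(np.ceil((end - start) / period - _EPS))
    onsets = start + period * np.arange(count)
    onsets = onsets[onsets < end - _EPS]
    return PulseTrain(tuple(onsets), width=width, amplitude=amplitude, label=label)


def build_default_protocol(
    trial_length: float = DEFAULT_TRIAL_MS,
    pulse_width: float = DEFAULT_PULSE_WIDTH_MS,
    ees_amplitude: float = 4.0,
    sensory_amplitude: float = 1.0,
    bootstrap_amplitude: float = 1.5,
) -> StimulusProtocol:
    """Assemble the default per-neuron protocol for one gait cycle.

    The sensory amplitude is a normalised pre-synaptic height; the
    effective amplitude reaching a neuron's adder is set by its input
    weight (fixed resistor or memristor transfer), see the circuit module.
    ``trial_length`` must cover the printed 250 ms window layout.
    """
    if trial_length < DEFAULT_TRIAL_MS:
        raise ValueError(
            f"trial_length must be >= {DEFAULT_TRIAL_MS} ms to hold the "
            f"sensory windows, got {trial_length}"
        )
    ees = generate_pulse_train(
        EES_FREQUENCY_HZ, (0.0, trial_length), ees_amplitude,
        width=pulse_width, trial_length=trial_length, label="ees",
    )
    channels: dict[str, dict[str, PulseTrain]] = {}
    for name in PATTERN_NEURONS:
        chans = {
            "ees": ees,
            "sensory": generate_pulse_train(
                SENSORY_FREQUENCY_HZ, SENSORY_WINDOWS_MS[name], sensory_amplitude,
                width=pulse_width, trial_length=trial_length,
                label=f"{name}/sensory",
            ),
        }
        if name in MEMRISTIVE_NEURONS:
            chans["bootstrap"] = generate_pulse_train(
                BOOTSTRAP_FREQUENCY_HZ, BOOTSTRAP_WINDOWS_MS[name],
                bootstrap_amplitude, width=pulse_width,
                trial_length=trial_length, label=f"{name}/bootstrap",
            )
        channels[name] = chans
    channels[MOTOR_NEURON] = {"ees": ees}
    return StimulusProtocol(trial_length=trial_length, channels=channels)


def rasterize(train: PulseTrain, dt: float, trial_length: float) -> np.ndarray:
    """Sample a pulse train onto a uniform grid of step ``dt``.

    Sample ``i`` covers ``[i*dt, (i+1)*dt)``; a pulse occupies the samples
    of ``[onset, onset+width)``.  ``dt`` must not exceed the pulse width
    (pulses would be skipped entirely).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt > train.width + _EPS:
        raise ValueError(
            f"dt={dt} exceeds pulse width {train.width}; pulses would be lost"
        )
    n = int(round(trial_length / dt))
    out = np.zeros(n)
    for onset in train.onset_times:
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + train.width) / dt)), n)
        if i0 < n:
            out[i0:i1] += train.amplitude
    return out


def detect_onsets(samples: np.ndarray, dt: float) -> np.ndarray:
    """Rising-edge times (ms) of a rasterized signal (inverse of rasterize)."""
    samples = np.asarray(samples)
    active = samples > 0
    rising = active & ~np.concatenate(([False], active[:-1]))
    return np.flatnonzero(rising) * dt
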