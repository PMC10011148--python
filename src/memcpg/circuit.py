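"""The two-nucleus CPG circuit: wiring, single trials, self-learning, calibration.

Five neurons: four pattern neurons (blue, yellow — fixed-resistor LNs;
pink, green — memristive MemNs) and one motor neuron (MN).  Each pattern
neuron sums its gated 200 Hz sensory train (amplitude set by its input
weight), the shared 20 Hz EES train and, for MemNs during learning, a
100 Hz bootstrap train; integrates the sum to spikes; and forwards the
spikes through a per-neuron delay to the MN, which sums the delayed
volleys with the EES train and integrates them into the circuit output.

Learning (:func:`run_learning`) alternates operation and adaptation:
within a trial all weights are frozen; between trials each MemN's 200 Hz
rising edges are paired nearest-neighbour with its output spikes, the
pairings are fed through the STDP learning function, and the summed
magnitude is written onto the memristor through the PWM stage.  With the
default potentiation-only rule the resistance decreases monotonically
until it reaches the 20 kOhm device floor, sharpening the late (>30 ms)
motor responses trial by trial.

:func:`calibrate` fixes the free electrical constants (threshold, leak
time constant, EES amplitude) by deterministic grid search against the
printed behavioral constraints (0/1/2 green-neuron spikes at 170/60/30
kOhm); :func:`calibrate_delays` measures each neuron's threshold-crossing
lag and compensates the synaptic delays so the evoked MN responses land at
the intended post-EES latencies (early ~10 ms, late 30-40 ms).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .device import (
    MemristorState,
    STDPParams,
    TransferCalibration,
    apply_pwm_update,
    pair_nearest,
    stdp_learning_signal,
    transfer_amplitude,
)
from .neuron import (
    LIFParams,
    MembraneTrace,
    NeuronConfig,
    adder,
    delay_block,
    integrate_membrane,
    spikes_to_pulses,
)
from .protocol import (
    MEMRISTIVE_NEURONS,
    MOTOR_NEURON,
    PATTERN_NEURONS,
    StimulusProtocol,
    build_default_protocol,
    rasterize,
)

__all__ = [
    "SimulationConfig",
    "CircuitConfig",
    "TrialResult",
    "LearningRun",
    "CalibrationResult",
    "CalibrationError",
    "run_trial",
    "run_learning",
    "run_control_resistor",
    "calibrate",
    "calibrate_delays",
    "DEFAULT_DELAY_TARGETS",
]

#: Intended post-EES arrival latency (ms) of each neuron's evoked MN
#: response: blue reproduces the early (10 ms) component, pink/green the
#: late 30-40 ms band.
DEFAULT_DELAY_TARGETS: Mapping[str, float] = {
    "blue": 10.0,
    "yellow": 20.0,
    "pink": 32.0,
    "green": 38.0,
}


class CalibrationError(RuntimeError):
    """No grid point satisfies the behavioral constraint set."""


@dataclass(frozen=True)
class SimulationConfig:
    """Discretisation and run-length settings.

    ``seed`` is reserved for optional stimulus jitter; the default
    simulator has no stochastic elements and ignores it.
    """

    dt: float = 0.1
    trial_length: float = 250.0
    n_trials: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.trial_length <= 0:
            raise ValueError(f"trial_length must be > 0, got {self.trial_length}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")


@dataclass(frozen=True)
class CircuitConfig:
    """Full description of the five-neuron circuit and its stimuli.

    ``mode`` selects how many plastic neurons learn: ``"single"`` (green
    learns, pink's input weight is a fixed resistor at the optimal
    ``fixed_pink_resistance``) or ``"dual"`` (pink and green both carry
    memristors).  ``bootstrap`` gates the 100 Hz trains in plain trials;
    learning runs enable it by default regardless (it exists to escape the
    zero-output deadlock of a fresh high-resistance device).
    """

    sim: SimulationConfig = SimulationConfig()
    lif: LIFParams = LIFParams()
    mn_lif: LIFParams = LIFParams(t_ref=5.0)
    stdp: STDPParams = STDPParams()
    transfer: TransferCalibration = TransferCalibration()
    r_min: float = 20.0
    r_max: float = 200.0
    mode: str = "dual"
    bootstrap: bool = False
    ees_amplitude: float = 4.0
    bootstrap_amplitude: float = 1.5
    sensory_amplitude: float = 1.0
    pulse_width: float = 1.0
    ln_resistance: float = 30.0
    fixed_pink_resistance: float = 25.0
    initial_resistance: Mapping[str, float] = field(
        default_factory=lambda: {"pink": 170.0, "green": 170.0}
    )
    delays: Mapping[str, float] = field(
        default_factory=lambda: {"blue": 10.0, "yellow": 20.0, "pink": 30.0, "green": 37.0}
    )

    def __post_init__(self) -> None:
        if self.mode not in ("single", "dual"):
            raise ValueError(f"mode must be 'single' or 'dual', got {self.mode!r}")
        if self.ln_resistance <= 0 or self.fixed_pink_resistance <= 0:
            raise ValueError("fixed input resistances must be > 0")
        if set(self.delays) != set(PATTERN_NEURONS):
            raise ValueError(f"delays must cover exactly {PATTERN_NEURONS}")
        if any(d < 0 for d in self.delays.values()):
            raise ValueError("delays must be >= 0")
        for name, r in self.initial_resistance.items():
            if name not in MEMRISTIVE_NEURONS:
                raise ValueError(f"initial_resistance for non-memristive {name!r}")
            if not (self.r_min <= r <= self.r_max):
                raise ValueError(
                    f"initial resistance {r} kOhm of {name!r} outside "
                    f"[{self.r_min}, {self.r_max}]"
                )
        object.__setattr__(self, "initial_resistance", dict(self.initial_resistance))
        object.__setattr__(self, "delays", dict(self.delays))

    @property
    def plastic_neurons(self) -> tuple[str, ...]:
        return ("green",) if self.mode == "single" else ("pink", "green")

    def build_protocol(self) -> StimulusProtocol:
        return build_default_protocol(
            trial_length=self.sim.trial_length,
            pulse_width=self.pulse_width,
            ees_amplitude=self.ees_amplitude,
            sensory_amplitude=self.sensory_amplitude,
            bootstrap_amplitude=self.bootstrap_amplitude,
        )

    def neuron_configs(
        self, resistances: Mapping[str, float] | None = None
    ) -> dict[str, NeuronConfig]:
        """The five per-neuron wiring records implied by this config."""
        res = dict(self.initial_resistance)
        if resistances:
            res.update(resistances)
        configs: dict[str, NeuronConfig] = {}
        for name in PATTERN_NEURONS:
            channels: tuple[str, ...] = ("sensory", "ees")
            if name in MEMRISTIVE_NEURONS and self.bootstrap:
                channels += ("bootstrap",)
            if name in self.plastic_neurons:
                kind = "MemN"
                weight: float | MemristorState = MemristorState(
                    res[name], r_min=self.r_min, r_max=self.r_max
                )
            elif name == "pink":  # single mode: fixed resistor at the optimum
                kind, weight = "LN", self.fixed_pink_resistance
            else:
                kind, weight = "LN", self.ln_resistance
            configs[name] = NeuronConfig(
                name=name, kind=kind, channels=channels, lif=self.lif,
                weight=weight, delay_to_mn=self.delays[name],
            )
        configs[MOTOR_NEURON] = NeuronConfig(
            name=MOTOR_NEURON, kind="MN", channels=("delayed", "ees"),
            lif=self.mn_lif,
        )
        return configs


@dataclass
class TrialResult:
    """Everything one 250 ms trial produced.

    ``mn_sources[i]`` names the pattern neuron whose delayed volley evoked
    ``mn_spikes[i]`` (or ``"ees"`` if none overlapped).  ``pairings`` maps
    each plastic neuron to its (t_pre, t_post, delta_t) STDP pairings.
    """

    dt: float
    trial_length: float
    traces: dict[str, MembraneTrace] | None
    spikes: dict[str, np.ndarray]
    mn_spikes: np.ndarray
    mn_sources: list[str]
    arrivals: list[tuple[float, str]]
    pairings: dict[str, list[tuple[float, float, float]]]
    resistances: dict[str, float]


@dataclass
class LearningRun:
    """Trajectory of a multi-trial self-learning experiment.

    ``trajectory[name]`` holds ``n_trials + 1`` resistance values: the
    initial state followed by the state after each trial's weight update.
    ``trials`` keeps the per-trial results (traces only on the last trial
    unless requested otherwise).
    """

    trials: list[TrialResult]
    trajectory: dict[str, np.ndarray]
    final_states: dict[str, MemristorState]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _sensory_gain(config: CircuitConfig, name: str, resistances: Mapping[str, float]) -> float:
    """Effective 200 Hz amplitude at a neuron's adder, per its input weight."""
    if name in config.plastic_neurons:
        return transfer_amplitude(
            config.transfer, resistances[name], config.r_min, config.r_max
        )
    if name == "pink":  # fixed resistor standing in for an optimally learned device
        return config.transfer.evaluate(config.fixed_pink_resistance)
    return config.transfer.evaluate(config.ln_resistance)


def run_trial(
    config: CircuitConfig,
    resistances: Mapping[str, float] | None = None,
    *,
    bootstrap: bool | None = None,
    record_traces: bool = True,
    gain_overrides: Mapping[str, float] | None = None,
) -> TrialResult:
    """Simulate one trial with frozen weights; fully deterministic.

    ``resistances`` overrides the memristor states for this trial (defaults
    to the config's initial resistances); ``bootstrap`` overrides the
    config's bootstrap flag; ``gain_overrides`` (used by the fixed-resistor
    control experiments) bypasses the weight model for named neurons.
    """
    proto = config.build_protocol()
    sim = config.sim
    dt, T = sim.dt, sim.trial_length
    boot = config.bootstrap if bootstrap is None else bootstrap
    res = dict(config.initial_resistance)
    if resistances:
        res.update(resistances)

    ees_raster = rasterize(proto.ees, dt, T)
    traces: dict[str, MembraneTrace] = {}
    spikes: dict[str, np.ndarray] = {}
    arrivals: list[tuple[float, str]] = []
    pairings: dict[str, list[tuple[float, float, float]]] = {}

    for name in PATTERN_NEURONS:
        chans = proto.channels[name]
        if gain_overrides and name in gain_overrides:
            gain = gain_overrides[name]
        else:
            gain = _sensory_gain(config, name, res)
        sensory = rasterize(chans["sensory"], dt, T) * gain
        inputs = [sensory, ees_raster]
        if boot and "bootstrap" in chans:
            inputs.append(rasterize(chans["bootstrap"], dt, T))
        trace = integrate_membrane(adder(inputs), config.lif, dt)
        traces[name] = trace
        spikes[name] = trace.spike_times
        for t in delay_block(trace.spike_times, config.delays[name]):
            arrivals.append((float(t), name))
        if name in config.plastic_neurons:
            pre = np.array(chans["sensory"].onset_times)
            pairings[name] = pair_nearest(pre, trace.spike_times)

    arrivals.sort()
    mn_drive = np.zeros_like(ees_raster)
    for t, _src in arrivals:
        mn_drive += spikes_to_pulses(
            [t], config.lif.pulse_amplitude, config.lif.pulse_width, dt, T
        )
    mn_trace = integrate_membrane(adder([mn_drive, ees_raster]), config.mn_lif, dt)
    traces[MOTOR_NEURON] = mn_trace
    spikes[MOTOR_NEURON] = mn_trace.spike_times

    slack = config.lif.pulse_width + 2 * dt
    sources = []
    for t_spike in mn_trace.spike_times:
        src = "ees"
        for t_arr, name in arrivals:
            if t_arr <= t_spike + 1e-9 <= t_arr + slack:
                src = name  # latest overlapping arrival wins
        sources.append(src)

    return TrialResult(
        dt=dt,
        trial_length=T,
        traces=traces if record_traces else None,
        spikes=spikes,
        mn_spikes=mn_trace.spike_times,
        mn_sources=sources,
        arrivals=arrivals,
        pairings=pairings,
        resistances={n: res[n] for n in MEMRISTIVE_NEURONS},
    )


def run_learning(
    config: CircuitConfig,
    *,
    n_trials: int | None = None,
    bootstrap: bool = True,
    record_traces: bool = False,
) -> LearningRun:
    """Iterate trials with between-trial STDP/PWM weight updates.

    The 100 Hz bootstrap is on by default (it is what lets a fresh
    high-resistance device produce the first output spikes, §learning
    deadlock); pass ``bootstrap=False`` to probe that necessity.  Weights
    are frozen within each trial and updated once per trial from the
    nearest-neighbour pre/post pairings.
    """
    n = config.sim.n_trials if n_trials is None else n_trials
    if n < 1:
        raise ValueError(f"n_trials must be >= 1, got {n}")
    states = {
        name: MemristorState(
            config.initial_resistance[name], r_min=config.r_min, r_max=config.r_max
        )
        for name in config.plastic_neurons
    }
    trajectory = {name: [states[name].resistance] for name in states}
    trials: list[TrialResult] = []
    for k in range(n):
        result = run_trial(
            config,
            {name: s.resistance for name, s in states.items()},
            bootstrap=bootstrap,
            record_traces=record_traces or (k == n - 1),
        )
        for name in config.plastic_neurons:
            magnitude = sum(
                stdp_learning_signal(config.stdp, d) for _, _, d in result.pairings[name]
            )
            states[name] = apply_pwm_update(states[name], config.stdp, magnitude)
            trajectory[name].append(states[name].resistance)
        trials.append(result)
    return LearningRun(
        trials=trials,
        trajectory={n_: np.array(v) for n_, v in trajectory.items()},
        final_states=states,
    )


def run_control_resistor(
    config: CircuitConfig, fixed_r: float, neurons: Sequence[str] = ("green",), **kwargs
) -> TrialResult:
    """One trial with plain resistors replacing the named memristors.

    The fixed resistance may lie below the memristive device floor (that
    is the point of the control experiment: emulate extremely low
    resistance); the amplitude comes from the transfer extrapolation.
    """
    if fixed_r <= 0:
        raise ValueError(f"control resistance must be > 0 kOhm, got {fixed_r}")
    gains = {name: config.transfer.evaluate(fixed_r) for name in neurons}
    return run_trial(config, gain_overrides=gains, **kwargs)


# --------------------------------------------------------------------------
# Calibration

#: Printed behavioral constraints: green-neuron spike count per device
#: resistance, with the single 60 kOhm spike pinned to the 200 ms EES
#: coincidence.
DEFAULT_CONSTRAINTS: tuple[tuple[float, int], ...] = ((170.0, 0), (60.0, 1), (30.0, 2))


@dataclass(frozen=True)
class CalibrationResult:
    """Feasible electrical constants found by the grid search."""

    lif: LIFParams
    ees_amplitude: float
    n_evaluated: int


def _green_spike_times(
    config: CircuitConfig,
    resistance: float,
    theta: float,
    tau_m: float,
    ees_amplitude: float,
) -> np.ndarray:
    """Green-neuron spikes for one candidate parameter set (bootstrap off)."""
    proto = build_default_protocol(
        trial_length=config.sim.trial_length,
        pulse_width=config.pulse_width,
        ees_amplitude=ees_amplitude,
        sensory_amplitude=config.sensory_amplitude,
        bootstrap_amplitude=config.bootstrap_amplitude,
    )
    dt, T = config.sim.dt, config.sim.trial_length
    gain = config.transfer.evaluate(resistance)
    u = rasterize(proto.channels["green"]["sensory"], dt, T) * gain
    u = u + rasterize(proto.ees, dt, T)
    params = replace(config.lif, threshold=theta, tau_m=tau_m)
    return integrate_membrane(u, params, dt).spike_times


def calibrate(
    config: CircuitConfig | None = None,
    constraints: Sequence[tuple[float, int]] = DEFAULT_CONSTRAINTS,
    *,
    taus: Sequence[float] = (6.0, 8.0, 10.0, 12.0),
    ees_amplitudes: Sequence[float] = (3.0, 3.5, 4.0, 4.5),
    thresholds: Sequence[float] | None = None,
    single_spike_window: tuple[float, float] = (200.0, 202.0),
) -> CalibrationResult:
    """Deterministic grid search for (threshold, tau_m, EES amplitude).

    A grid point is feasible when the green-neuron trial (bootstrap off)
    reproduces every ``(resistance, spike count)`` constraint, with any
    single-spike scenario firing inside ``single_spike_window`` (the
    200 ms EES coincidence).  Returns the first feasible point in grid
    order; raises :class:`CalibrationError` if the grid holds none or the
    constraint set is self-contradictory.
    """
    config = config or CircuitConfig()
    seen: dict[float, int] = {}
    for r, count in constraints:
        if r in seen and seen[r] != count:
            raise CalibrationError(
                f"contradictory constraints: {r} kOhm -> {seen[r]} and {count} spikes"
            )
        seen[r] = count
    if thresholds is None:
        thresholds = np.round(np.arange(0.50, 0.801, 0.02), 3)
    n_eval = 0
    for tau in taus:
        for a20 in ees_amplitudes:
            for theta in thresholds:
                n_eval += 1
                ok = True
                for r, count in constraints:
                    spikes = _green_spike_times(config, r, float(theta), tau, a20)
                    if spikes.size != count:
                        ok = False
                        break
                    if count == 1 and not (
                        single_spike_window[0] <= spikes[0] <= single_spike_window[1]
                    ):
                        ok = False
                        break
                if ok:
                    return CalibrationResult(
                        lif=replace(config.lif, threshold=float(theta), tau_m=tau),
                        ees_amplitude=a20,
                        n_evaluated=n_eval,
                    )
    raise CalibrationError(
        f"no feasible (threshold, tau_m, EES amplitude) on the {n_eval}-point grid"
    )


def _ees_offsets(spike_times: np.ndarray, ees_onsets: np.ndarray) -> np.ndarray:
    """Latency of each spike to the most recent EES rising edge."""
    offsets = []
    for t in spike_times:
        prior = ees_onsets[ees_onsets <= t + 1e-9]
        if prior.size:
            offsets.append(t - prior[-1])
    return np.array(offsets)


def calibrate_delays(
    config: CircuitConfig,
    targets: Mapping[str, float] = DEFAULT_DELAY_TARGETS,
    probe_resistance: float = 25.0,
) -> dict[str, float]:
    """Compensate synaptic delays for the integrator threshold-crossing lag.

    A neuron crosses threshold a fraction of a millisecond into the
    coincident pulse, and the MN adds its own lag; raw delays would push
    the evoked responses slightly past their intended latencies.  This
    probe trial (memristors pinned to the mid-optimal ``probe_resistance``)
    measures the mean lag per neuron plus the MN lag on an isolated
    volley, and returns delays such that each neuron's responses arrive at
    ``targets[name]`` ms after the EES pulse.
    """
    probe = run_trial(
        config,
        {name: probe_resistance for name in MEMRISTIVE_NEURONS},
        bootstrap=False,
    )
    proto = config.build_protocol()
    ees_onsets = np.array(proto.ees.onset_times)
    dt, T = config.sim.dt, config.sim.trial_length

    # MN lag: a single volley at 25 ms, far from any EES pulse.
    lone = spikes_to_pulses(
        [25.0], config.lif.pulse_amplitude, config.lif.pulse_width, dt, T
    )
    mn_probe = integrate_membrane(
        adder([lone, rasterize(proto.ees, dt, T)]), config.mn_lif, dt
    )
    if mn_probe.spike_times.size == 0:
        raise CalibrationError("MN does not respond to a lone afferent volley")
    mn_lag = float(mn_probe.spike_times[0] - 25.0)

    delays: dict[str, float] = {}
    for name in PATTERN_NEURONS:
        offs = _ees_offsets(probe.spikes[name], ees_onsets)
        if offs.size == 0:
            raise CalibrationError(f"probe trial produced no {name} spikes")
        delays[name] = max(0.0, targets[name] - float(offs.mean()) - mn_lag)
    return delays
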