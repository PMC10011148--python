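# Methods

## Scope and modelling level

`memcpg` is a *behavioral* simulator: it reproduces the signal-level
behavior of a five-neuron memristive CPG board — pulse protocols,
amplitude transfer through the memristive integration block, leaky
integrate-and-fire dynamics, STDP-driven resistance updates and the
motor-neuron delay structure — without simulating the underlying
electronics (no op-amp adders, no PWM waveforms, no electrochemical
kinetics of the polyaniline device, no I–V hysteresis, endurance or
retention effects).  Everything is deterministic: two runs from one
configuration produce byte-identical outputs.

## Stimulus protocol

One trial is a 250 ms gait cycle sampled at dt = 0.1 ms.  All trains are
rectangular pulses of width 1 ms.  Windows are half-open `[start, end)` so
a 200 Hz window holds exactly 20 pulses and a trial exactly 5 EES pulses;
the published description of "one output per five input stimuli" is
arithmetically ambiguous, and the half-open reading (5 EES pulses/trial,
the 60 kΩ neuron firing once per trial at the 200 ms coincidence) is the
one consistent with the recorded traces.

| train | frequency | windows | amplitude (default) |
|---|---|---|---|
| EES | 20 Hz | [0, 250) shared | 4.0 V |
| sensory | 200 Hz | blue [0,100), yellow [50,150), pink [100,200), green [150,250) | A(R), see below |
| bootstrap | 100 Hz | pink [100,200), green [150,250) | 1.5 V |

## Memristor model

*Read path.*  The 200 Hz amplitude at a neuron's adder is `A(R)`,
calibrated on the measured anchors (30 kΩ, 1.6 V), (60 kΩ, 0.85 V),
(170 kΩ, 0.4 V): monotone shape-preserving (PCHIP) interpolation between
anchors, linear-in-conductance extrapolation outside their span (through
the two nearest anchors; below 30 kΩ this gives `A = 0.1 + 45/R`, e.g.
2.35 V at the 20 kΩ floor), clamped to ≥ 0.  The three printed points do
not fit a single two-parameter divider law, which is why interpolation is
used rather than a global fit.  Device bounds are 20–200 kΩ: learning
runs terminate at 20 kΩ and the largest reported initial state is 170 kΩ.
The set/reset voltage gates of the physical device are retained as state
(`apply_write_voltage`) for characterisation, but the learning loop always
writes through the PWM path.

*Write path.*  The learning-feedback function is exponential pair-based
STDP on nearest-neighbour (pre = 200 Hz rising edge, post = output spike)
pairs: potentiation `A₊·exp(−Δt/τ₊)` for 0 < Δt ≤ W, depression
`−A₋·exp(Δt/τ₋)` for −W ≤ Δt < 0, zero outside.  Defaults: A₊ = 1.2e−4
kΩ⁻¹, A₋ = 0 (the hardware runs report only monotone resistance
decrease), τ± = 10 ms, W = 25 ms, PWM gain 1.  The exact hardware learning
function and duty-cycle mapping live in supplementary circuit schematics
that the model does not reproduce; the exponential rule with a scalar
write gain is this package's declared stand-in, fully exposed in config.
A₊ was chosen analytically: at high resistance a trial yields ≈3·A₊ of
conductance gain, so the 170→20 kΩ traversal (ΔG ≈ 0.044 kΩ⁻¹) completes
in well under the 200-trial default horizon.  Updates act on conductance
and are clipped to the device range, making the floor absorbing.

## Neuron model

Discrete leaky integrator, `V[t+dt] = V·exp(−dt/τ_m) + u·dt/τ_m`, so a
sustained input of amplitude A saturates the membrane at A.  On reaching
the threshold the neuron emits a spike (recorded at the grid time of the
crossing), resets to V_reset = −0.5 V and ramps linearly back to 0 V over
the refractory period t_ref, during which all input is discarded.
t_ref = 15 ms for pattern neurons, matching the recorded sub-zero
interval (spike at ~200 ms, recovery at ~215 ms).  The motor neuron uses
t_ref = 5 ms: afferent volleys from adjacent delay paths arrive 6–10 ms
apart and the recorded outputs show both responses, which a 15 ms MN
refractory would swallow; the MN refractory is not reported for the
hardware.  Output spikes are instantaneous events rasterized as 10 V ×
1 ms pulses for downstream adders.  Whether the hardware leak is
exponential or linear is not stated; exponential (standard LIF) is used.

## Calibration of free constants

The board's electrical constants are not published; they are fixed by the
three recorded green-neuron scenarios — 0 spikes at 170 kΩ, 1 spike at
the 200 ms coincidence at 60 kΩ, 2 spikes at 30 kΩ.  `calibrate()` is a
deterministic grid search over (θ, τ_m, EES amplitude) that replays those
scenarios and returns the first feasible point; the package defaults
θ = 0.63 V, τ_m = 8 ms, EES 4.0 V lie inside the feasible region and
additionally keep the 200 Hz train alone sub-threshold at the 20 kΩ
floor, so the learned circuit stays in the coincidence-firing "optimal"
pattern rather than free-running.  The bootstrap amplitude 1.5 V is
sub-threshold alone but supra-threshold summed with the 20+200 Hz trains
at high resistance — exactly the property that lets a fresh device escape
the zero-output deadlock.  Fixed-weight neurons (blue/yellow, and pink in
single-plastic mode) use resistances 30 kΩ and 25 kΩ: values in or at the
optimal band, since the hardware's resistor values are unreported.

Synaptic delays are design parameters whose purpose is the delay
structure itself: early responses at ~10 ms post-EES through blue, late
responses in the 30–40 ms band through pink/green.  Raw defaults are
blue 10 / yellow 20 / pink 30 / green 37 ms.  Because a neuron crosses
threshold a fraction of a millisecond into the coincident pulse, and the
MN adds its own ~0.6 ms lag, `calibrate_delays()` measures those lags in
a probe trial and compensates the delays so responses arrive at targets
blue 10 / yellow 20 / pink 32 / green 38 ms (±0.3 ms residual jitter from
state-dependent crossing times).  Pink/green targets are mid-band values
of the 30–40 ms late-response frame.

One structural consequence of the leak kinetics: a pattern neuron whose
sensory window closes exactly on an EES pulse (blue at 100 ms, yellow at
150 ms, pink at 200 ms) retains enough 200 Hz residual for that EES pulse
to fire it once more.  These "echo" responses arrive at the neuron's
standard latency and do not disturb the early/late classification.

## Trials, learning and evaluation

Weights are frozen within a trial and updated once between trials
(batch-per-trial STDP) — mirroring the conceptual separation of operation
and learning phases and keeping single trials linear-time.  The 100 Hz
bootstrap defaults to ON in `run_learning` (it is a learning aid) and OFF
in plain `run_trial` evaluation, matching the recorded single-trial
traces which contain only the 20+200 Hz sums; both are config switches,
and the bootstrap is kept on throughout learning (no withdrawal schedule
is reported).  In single-plastic mode only green learns and pink's weight
is a fixed 25 kΩ resistor ("set to be optimal"); dual-plastic mode learns
both.  Learning runs default to 200 trials; the hardware's trial count is
unreported, so endpoints are asserted as band/floor targets rather than
trial-indexed values.  The default run sizes (250 ms × 2500 steps × 5
neurons × 200 trials ≈ 2.5 M integrator steps, ~1 s) were chosen so a
complete experiment is interactive on one CPU.

Metrics: MN spikes are classified by latency to the most recent EES pulse
— early [0, 15] ms, late [30, 45] ms (brackets around the reported 10 ms
and 30–40 ms components), else intermediate; spikes preceding the first
EES pulse are reported separately.  Sub-threshold MN depolarisations are
not counted as responses.  Resistance regimes follow the observed bands
(>70 kΩ no output, 40–60 sparse, 20–30 optimal, <1 ruined) with the gaps
left `unclassified` rather than interpolated.  Each MN spike is
attributed to the latest delayed volley overlapping its crossing time,
enabling per-source latency analysis.

## What the simulator does and does not show

Passing tests demonstrate that the *model circuit* reproduces the
qualitative and quantitative structure of the hardware observations:
anchor-exact amplitude transfer, the 0/1/2 spike-count regimes, 15 ms
refractory, monotone learning to the device floor, bootstrap necessity,
and the early/late latency split.  They do not validate device physics
(switching kinetics, variability, drift), electrical non-idealities, or
behavior under biological, noisy or closed-loop inputs — the stimulus
generator is noise-free and perfectly periodic, where real plantar
afferents and EES electrodes are not.  A `seed` field is reserved in the
simulation config for optional stimulus jitter; the default model uses no
randomness.

## Numerical choices and degenerate inputs

dt = 0.1 ms (40 samples per 200 Hz period; halving dt shifts crossing
times by < 0.1 ms).  Rasterization maps times to grid indices by
rounding, so trains whose onsets sit on the grid round-trip exactly
through onset detection.  Ties in nearest-neighbour pairing break toward
the causal (positive Δt) pair.  Degenerate inputs fail fast with
`ValueError`/`ConfigError`: non-positive frequencies, windows outside the
trial, dt coarser than the pulse width, zero trial counts, non-positive
resistances, contradictory calibration constraints
(`CalibrationError`).

## Configuration schema

YAML/JSON sections (all keys optional; unknown keys rejected):
`simulation` (dt_ms 0.1, trial_length_ms 250, n_trials 200, seed 0),
`protocol` (pulse_width_ms 1, ees_amplitude_v 4, sensory_amplitude_v 1,
bootstrap_amplitude_v 1.5), `lif` (threshold_v 0.63, tau_m_ms 8,
reset_v −0.5, refractory_ms 15, pulse_amplitude_v 10, pulse_width_ms 1),
`motor` (same fields, refractory_ms 5), `device` (r_min_kohm 20,
r_max_kohm 200, anchors), `stdp` (a_plus 1.2e−4, a_minus 0, tau_plus_ms /
tau_minus_ms 10, window_ms 25, pwm_gain 1), `circuit` (mode dual,
bootstrap false, ln_resistance_kohm 30, fixed_pink_kohm 25,
initial_r_kohm {pink 170, green 170}, delays_ms {10, 20, 30, 37}).
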