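# memcpg

A behavioral simulator of a **memristive central pattern generator (CPG)**:
a minimal spinal-like circuit of five leaky integrate-and-fire (LIF)
neurons in which two neurons carry plastic organic-memristor input
weights, and spike-timing-dependent plasticity (STDP) self-tunes those
weights until the motor output reproduces the early (~10 ms) and late
(>30 ms) evoked-response delay structure seen during locomotion
facilitated by epidural electrical stimulation (EES).

The intended audience is researchers in neuromorphic engineering and
neurostimulation who want a deterministic, desk-scale software twin of
such a circuit: to explore stimulus protocols, plasticity parameters and
resistance regimes before (or instead of) wiring hardware.

## The circuit and its model

Four *pattern neurons* (blue, yellow, pink, green) each receive:

* a **200 Hz sensory train** gated to a 100 ms window, staggered heel-to-toe
  across the 250 ms gait cycle (blue 0–100, yellow 50–150, pink 100–200,
  green 150–250 ms);
* the shared **20 Hz EES train** (pulses at 0, 50, 100, 150, 200 ms);
* for the two memristive neurons, an optional **100 Hz bootstrap train**
  that kick-starts learning while the device is still too resistive to fire.

The 200 Hz pulses pass through a memristive integration block whose output
amplitude `A(R)` falls with device resistance; it is calibrated on the
measured anchors `A(30) = 1.6 V`, `A(60) = 0.85 V`, `A(170) = 0.4 V`
(monotone PCHIP interpolation, linear-in-1/R extrapolation).  Each neuron
sums its channels and integrates them with exponential leak:

    V[t+dt] = V[t] · exp(−dt/τ_m) + u[t] · dt/τ_m

spiking at threshold θ, then resetting to `V_reset < 0` with a 15 ms
refractory ramp during which input is ignored.  Spikes travel through
per-neuron delays to the motor neuron (MN), which integrates the delayed
volleys plus the EES train into the circuit output.

Learning alternates operation and adaptation: within a trial weights are
frozen; between trials each memristive neuron's 200 Hz rising edges are
paired nearest-neighbour with its output spikes, and each causal pair
`Δt = t_post − t_pre ∈ (0, W]` potentiates the device by
`ΔG = A₊ · exp(−Δt/τ₊)` (conductance increase = resistance decrease),
written through a pulse-width-modulation stage abstracted to a scalar
gain and clipped to the 20–200 kΩ device range.

## Worked example

```python
from memcpg import CircuitConfig, run_trial

config = CircuitConfig()
for r in (170.0, 60.0, 30.0):
    result = run_trial(config, {"green": r}, bootstrap=False)
    print(r, result.spikes["green"])
```

prints

```
170.0 []
60.0 [200.9]
30.0 [151.  200.6]
```

i.e. the three observed spike-count regimes of the green neuron: at
170 kΩ the attenuated 200 Hz train never reaches threshold; at 60 kΩ only
the second 20/200 Hz coincidence (the EES pulse at 200 ms) fires; at
30 kΩ both coincidences fire.  A full self-learning run
(`examples/02_self_learning_run.py`):

```
green: R at trials 0/25/50/100/200 = 120.0, 56.7, 37.0, 20.0, 20.0 kOhm
pink:  R at trials 0/25/50/100/200 =  70.0, 36.6, 23.8, 20.0, 20.0 kOhm
```

shows both memristors descending monotonically to the 20 kΩ device floor,
and the post-learning trial (`examples/03_latency_structure.py`) yields
motor responses at ~10 ms post-EES via the blue neuron (early) and at
31–38 ms via the memristive neurons (late) — the delay structure the
circuit is built to learn.

Further examples: `examples/01_single_trial_spike_regimes.py` and
`examples/04_control_resistor.py` (a fixed 1 kΩ resistor in place of the
memristor, which ruins the pattern).

## Command line

```bash
memcpg simulate -o out/trial --r-green 30 --no-bootstrap   # one trial
memcpg learn    -o out/learn --mode dual                   # learning run
memcpg calibrate                                           # grid-search free constants
memcpg sweep    -o out/sweep --resistances 170,60,30       # spike counts vs R
```

Outputs are plain CSV/JSON with a checksum manifest; identical configs
reproduce byte-identical files.  Config files are YAML/JSON; every key is
optional (see `docs/methods.md` for the schema and defaults), unknown keys
are rejected.  Exit codes: 0 ok, 1 infeasible calibration, 2 bad input.

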