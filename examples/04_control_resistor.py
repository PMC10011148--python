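"""Fixed 1 kOhm resistor in place of the green memristor: a ruined pattern.

At extremely low input resistance a single 200 Hz pulse is enough to reach
threshold, so the neuron fires off-coincidence and the motor output loses
its clean early/late structure ("responses appear chaotically").
"""
from dataclasses import replace

from memcpg import (
    CircuitConfig,
    calibrate_delays,
    classify_responses,
    regime_classify,
    run_control_resistor,
    run_trial,
    slice_spike_counts,
)

config = CircuitConfig(mode="dual")
tuned = replace(config, delays=calibrate_delays(config))
ees = tuned.build_protocol().ees.onset_times

memristive = run_trial(tuned, {"pink": 25.0, "green": 30.0}, bootstrap=False)
control = run_control_resistor(tuned, 1.0, resistances={"pink": 25.0}, bootstrap=False)

for label, result in (("memristor 30 kOhm", memristive), ("resistor 1 kOhm", control)):
    counts = "/".join(str(c) for c in slice_spike_counts(result.mn_spikes, 250.0))
    cls, _ = classify_responses(result.mn_spikes, ees, sources=result.mn_sources)
    green = [(round(c.latency, 1), c.label) for c in cls if c.source == "green"]
    print(f"{label}: green spikes {result.spikes['green'].size}, "
          f"MN spikes per 50 ms slice {counts}, green-evoked {green}")

print("\nregime labels:", regime_classify(30.0).label, "vs", regime_classify(0.9).label)
print(
    "\nThe 1 kOhm control multiplies green firing and injects responses at"
    "\nearly/intermediate latencies that the memristive circuit does not show."
)
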