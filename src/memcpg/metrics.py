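"""Quantify simulator output in the terms used for EES-facilitated locomotion.

Motor-neuron spikes are described by their latency to the most recent EES
pulse and classified as *early* (~10 ms, monosynaptic-like), *late*
(30-45 ms band, the plastically shaped component) or *intermediate*.
Device resistances are mapped onto the behavioral regimes observed in the
hardware experiments, and trials are summarised per 50 ms gait-cycle
slice.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ResponseClassification",
    "RegimeLabel",
    "classify_responses",
    "regime_classify",
    "slice_spike_counts",
    "summarize_trial",
    "EARLY_BAND_MS",
    "LATE_BAND_MS",
]

#: Latency bands (ms, inclusive) bracketing the printed 10 ms early and
#: 30-40 ms late response components.
EARLY_BAND_MS = (0.0, 15.0)
LATE_BAND_MS = (30.0, 45.0)

#: Resistance regimes (kOhm): printed bands, gaps left unclassified.
_REGIME_BANDS = (
    ("no_output", 70.0, float("inf")),   # R > 70: too resistive to fire
    ("sparse", 40.0, 60.0),              # one output per trial
    ("optimal", 20.0, 30.0),             # fires at every 20/200 Hz coincidence
    ("ruined", 0.0, 1.0),                # R < 1: pattern collapses
)


@dataclass(frozen=True)
class ResponseClassification:
    """One MN spike: its EES-relative latency and latency class."""

    spike_time: float
    latency: float
    label: str
    source: str = ""


@dataclass(frozen=True)
class RegimeLabel:
    """Behavioral regime of a device resistance value."""

    label: str
    band: tuple[float, float]


def classify_responses(
    mn_spikes: Sequence[float],
    ees_onsets: Sequence[float],
    early: tuple[float, float] = EARLY_BAND_MS,
    late: tuple[float, float] = LATE_BAND_MS,
    sources: Sequence[str] | None = None,
) -> tuple[list[ResponseClassification], list[float]]:
    """Classify every MN spike by its latency to the preceding EES pulse.

    Returns ``(classified, unclassifiable)``; a spike preceding the first
    EES pulse has no reference edge and is reported separately.  Each
    spike is classified exactly once.
    """
    ees = np.sort(np.asarray(ees_onsets, dtype=float))
    if ees.size == 0:
        raise ValueError("ees_onsets must be non-empty")
    classified: list[ResponseClassification] = []
    orphans: list[float] = []
    for i, t in enumerate(np.asarray(mn_spikes, dtype=float)):
        prior = ees[ees <= t + 1e-9]
        if prior.size == 0:
            orphans.append(float(t))
            continue
        latency = float(t - prior[-1])
        if early[0] <= latency <= early[1]:
            label = "early"
        elif late[0] <= latency <= late[1]:
            label = "late"
        else:
            label = "intermediate"
        classified.append(
            ResponseClassification(
                spike_time=float(t),
                latency=latency,
                label=label,
                source=sources[i] if sources is not None else "",
            )
        )
    return classified, orphans


def regime_classify(resistance: float) -> RegimeLabel:
    """Map a device resistance (kOhm) onto its behavioral regime.

    Bands follow the hardware observations: >70 kOhm no output, 40-60
    kOhm sparse (one output per trial), 20-30 kOhm optimal (a spike at
    every 20/200 Hz coincidence), <1 kOhm ruined.  Resistances in the
    gaps between printed bands are reported ``unclassified`` rather than
    assigned by extrapolation.
    """
    if resistance <= 0:
        raise ValueError(f"resistance must be > 0 kOhm, got {resistance}")
    for label, lo, hi in _REGIME_BANDS:
        if label == "no_output" and resistance > lo:
            return RegimeLabel(label, (lo, hi))
        if label == "ruined" and resistance < hi:
            return RegimeLabel(label, (lo, hi))
        if label in ("sparse", "optimal") and lo <= resistance <= hi:
            return RegimeLabel(label, (lo, hi))
    return RegimeLabel("unclassified", (np.nan, np.nan))


def slice_spike_counts(
    spikes: Sequence[float], trial_length: float, slice_width: float = 50.0
) -> np.ndarray:
    """Spike counts over consecutive half-open slices of the trial.

    ``slice_width`` must divide ``trial_length``; counts sum to the number
    of spikes inside ``[0, trial_length)``.
    """
    n_slices = trial_length / slice_width
    if abs(n_slices - round(n_slices)) > 1e-9:
        raise ValueError(
            f"slice_width {slice_width} must divide trial_length {trial_length}"
        )
    n_slices = int(round(n_slices))
    counts = np.zeros(n_slices, dtype=int)
    for t in np.asarray(spikes, dtype=float):
        if 0 <= t < trial_length:
            counts[int(t // slice_width)] += 1
    return counts


def summarize_trial(result, config=None) -> dict:
    """JSON-ready summary of one trial: slice counts, latencies, regimes."""
    from .protocol import MEMRISTIVE_NEURONS  # local to avoid cycle at import

    ees = None
    if config is not None:
        ees = list(config.build_protocol().ees.onset_times)
    else:
        ees = [50.0 * k for k in range(int(result.trial_length // 50))]
    classified, orphans = classify_responses(
        result.mn_spikes, ees, sources=result.mn_sources
    )
    return {
        "mn_slice_counts": slice_spike_counts(
            result.mn_spikes, result.trial_length
        ).tolist(),
        "responses": [
            {
                "spike_time_ms": c.spike_time,
                "latency_ms": c.latency,
                "class": c.label,
                "source": c.source,
            }
            for c in classified
        ],
        "unclassifiable_spikes_ms": orphans,
        "regimes": {
            name: regime_classify(r).label
            for name, r in result.resistances.items()
            if name in MEMRISTIVE_NEURONS
        },
        "resistances_kohm": dict(result.resistances),
    }
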