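"""Deterministic output writing: CSV traces, JSON summaries, run manifests.

All files are plain text with fixed formatting (header row, '.' decimal
separator, units in the column names, sorted JSON keys), so re-running an
identical configuration reproduces byte-identical outputs — the manifest's
checksums are the reproducibility contract.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .circuit import CircuitConfig, LearningRun, TrialResult
from .config import config_to_dict
from .metrics import summarize_trial

__all__ = ["RunManifest", "write_outputs"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    """Inventory of one run's outputs with content checksums."""

    config: dict
    version: str
    files: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "version": self.version, "files": self.files}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _trial_frames(result: TrialResult) -> dict[str, pd.DataFrame]:
    frames: dict[str, pd.DataFrame] = {}
    if result.traces is not None:
        rows = []
        for name, trace in result.traces.items():
            times = trace.times
            rows.append(
                pd.DataFrame(
                    {"time_ms": times, "neuron": name, "V": trace.potential}
                )
            )
        frames["traces.csv"] = pd.concat(rows, ignore_index=True)
    spike_rows = [
        {"neuron": name, "spike_time_ms": float(t)}
        for name, times in result.spikes.items()
        for t in times
    ]
    frames["spikes.csv"] = pd.DataFrame(
        spike_rows, columns=["neuron", "spike_time_ms"]
    )
    return frames


def write_outputs(
    results: TrialResult | LearningRun,
    outdir: str | Path,
    config: CircuitConfig | None = None,
) -> RunManifest:
    """Write a trial's or learning run's files into ``outdir``.

    Trials produce ``traces.csv``/``spikes.csv``/``summary.json``;
    learning runs add ``resistance_trajectory.csv`` (one row per trial per
    plastic neuron, the post-update state) and summarise the final trial.
    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    frames: dict[str, pd.DataFrame] = {}
    summary: dict = {}
    if isinstance(results, LearningRun):
        rows = [
            {"trial_index": k + 1, "neuron": name, "R_kOhm": float(r)}
            for name, traj in sorted(results.trajectory.items())
            for k, r in enumerate(traj[1:])
        ]
        frames["resistance_trajectory.csv"] = pd.DataFrame(
            rows, columns=["trial_index", "neuron", "R_kOhm"]
        )
        summary["n_trials"] = results.n_trials
        summary["final_resistances_kohm"] = {
            name: s.resistance for name, s in results.final_states.items()
        }
        summary["initial_resistances_kohm"] = {
            name: float(traj[0]) for name, traj in results.trajectory.items()
        }
        if results.trials:
            last = results.trials[-1]
            frames.update(_trial_frames(last))
            summary["final_trial"] = summarize_trial(last, config)
    else:
        frames.update(_trial_frames(results))
        summary = summarize_trial(results, config)

    manifest = RunManifest(
        config=config_to_dict(config) if config is not None else {},
        version=__version__,
    )
    for name, frame in sorted(frames.items()):
        path = outdir / name
        try:
            frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        manifest.files[name] = _sha256(path)
    _write_json(outdir / "summary.json", summary)
    manifest.files["summary.json"] = _sha256(outdir / "summary.json")
    _write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest
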