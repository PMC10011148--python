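"""Optional figure helpers (requires the ``plots`` extra / matplotlib).

Renders the two standard views of a run: per-neuron membrane traces over
one trial, and memristor resistance trajectories across a learning run.
"""
from __future__ import annotations

from pathlib import Path

__all__ = ["plot_membrane_traces", "plot_resistance_trajectories"]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_membrane_traces(result, path: str | Path, threshold: float | None = None):
    """One panel per neuron: membrane potential and spike markers."""
    if result.traces is None:
        raise ValueError("trial was run without record_traces")
    plt = _pyplot()
    names = list(result.traces)
    fig, axes = plt.subplots(len(names), 1, sharex=True, figsize=(8, 1.8 * len(names)))
    for ax, name in zip(axes, names):
        trace = result.traces[name]
        ax.plot(trace.times, trace.potential, lw=0.8, color="tab:blue")
        for t in trace.spike_times:
            ax.axvline(t, color="tab:red", lw=0.6, alpha=0.7)
        if threshold is not None:
            ax.axhline(threshold, color="tab:green", lw=0.6, ls="--")
        ax.set_ylabel(f"{name}\nV")
    axes[-1].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_resistance_trajectories(run, path: str | Path):
    """Resistance (kOhm) of each plastic neuron across learning trials."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, traj in sorted(run.trajectory.items()):
        ax.plot(range(len(traj)), traj, label=name, color=name if name != "mn" else None)
    ax.set_xlabel("trial")
    ax.set_ylabel("memristor resistance (kOhm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
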