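"""Structured text configuration: YAML/JSON <-> :class:`CircuitConfig`.

The file schema mirrors the physical structure of the rig::

    simulation: {dt_ms, trial_length_ms, n_trials, seed}
    protocol:   {pulse_width_ms, ees_amplitude_v, sensory_amplitude_v,
                 bootstrap_amplitude_v}
    lif:        {threshold_v, tau_m_ms, reset_v, refractory_ms,
                 pulse_amplitude_v, pulse_width_ms}
    motor:      {threshold_v, tau_m_ms, reset_v, refractory_ms}
    device:     {r_min_kohm, r_max_kohm, v_set, v_reset, anchors}
    stdp:       {a_plus, a_minus, tau_plus_ms, tau_minus_ms, window_ms,
                 pwm_gain}
    circuit:    {mode, bootstrap, ln_resistance_kohm, fixed_pink_kohm,
                 initial_r_kohm: {pink, green}, delays_ms: {...}}

Every key is optional (defaults per the calibrated circuit); unknown keys
are rejected with a field-level message, and a save -> load round trip is
the identity.
"""
from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import yaml

from .circuit import CircuitConfig, SimulationConfig
from .device import STDPParams, TransferCalibration
from .neuron import LIFParams

__all__ = ["ConfigError", "load_config", "save_config", "config_to_dict", "config_from_dict"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


def _take(section: dict, path: str, mapping: dict[str, str]) -> dict:
    """Translate file keys to constructor kwargs, rejecting unknown keys."""
    out = {}
    for key, value in section.items():
        if key not in mapping:
            raise ConfigError(f"{path}.{key}: unknown key")
        out[mapping[key]] = value
    return out


def config_from_dict(data: dict) -> CircuitConfig:
    """Build a validated config from a (possibly partial) nested dict."""
    if not isinstance(data, dict):
        raise ConfigError("top level must be a mapping")
    known = {"simulation", "protocol", "lif", "motor", "device", "stdp", "circuit"}
    for key in data:
        if key not in known:
            raise ConfigError(f"{key}: unknown section")
    try:
        sim = SimulationConfig(**_take(data.get("simulation", {}), "simulation", {
            "dt_ms": "dt", "trial_length_ms": "trial_length",
            "n_trials": "n_trials", "seed": "seed",
        }))
        lif_kwargs = _take(data.get("lif", {}), "lif", {
            "threshold_v": "threshold", "tau_m_ms": "tau_m", "reset_v": "v_reset",
            "refractory_ms": "t_ref", "pulse_amplitude_v": "pulse_amplitude",
            "pulse_width_ms": "pulse_width",
        })
        lif = LIFParams(**lif_kwargs)
        mn_kwargs = _take(data.get("motor", {}), "motor", {
            "threshold_v": "threshold", "tau_m_ms": "tau_m", "reset_v": "v_reset",
            "refractory_ms": "t_ref",
        })
        mn_defaults = {"t_ref": 5.0}
        mn_defaults.update(mn_kwargs)
        mn_lif = replace(lif, **mn_defaults)
        stdp = STDPParams(**_take(data.get("stdp", {}), "stdp", {
            "a_plus": "a_plus", "a_minus": "a_minus", "tau_plus_ms": "tau_plus",
            "tau_minus_ms": "tau_minus", "window_ms": "window", "pwm_gain": "pwm_gain",
        }))
        dev = _take(data.get("device", {}), "device", {
            "r_min_kohm": "r_min", "r_max_kohm": "r_max",
            "v_set": "v_set", "v_reset": "v_reset", "anchors": "anchors",
        })
        transfer = TransferCalibration(
            tuple(tuple(a) for a in dev["anchors"])
        ) if "anchors" in dev else TransferCalibration()
        proto = _take(data.get("protocol", {}), "protocol", {
            "pulse_width_ms": "pulse_width", "ees_amplitude_v": "ees_amplitude",
            "sensory_amplitude_v": "sensory_amplitude",
            "bootstrap_amplitude_v": "bootstrap_amplitude",
        })
        circ = _take(data.get("circuit", {}), "circuit", {
            "mode": "mode", "bootstrap": "bootstrap",
            "ln_resistance_kohm": "ln_resistance",
            "fixed_pink_kohm": "fixed_pink_resistance",
            "initial_r_kohm": "initial_resistance", "delays_ms": "delays",
        })
        if "delays" in circ:
            base = {"blue": 10.0, "yellow": 20.0, "pink": 30.0, "green": 37.0}
            base.update(circ["delays"])
            circ["delays"] = base
        if "initial_resistance" in circ:
            base = {"pink": 170.0, "green": 170.0}
            base.update(circ["initial_resistance"])
            circ["initial_resistance"] = base
        return CircuitConfig(
            sim=sim, lif=lif, mn_lif=mn_lif, stdp=stdp, transfer=transfer,
            r_min=dev.get("r_min", 20.0), r_max=dev.get("r_max", 200.0),
            **proto, **circ,
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: CircuitConfig) -> dict:
    """Serialise a config to the documented file schema."""
    return {
        "simulation": {
            "dt_ms": config.sim.dt,
            "trial_length_ms": config.sim.trial_length,
            "n_trials": config.sim.n_trials,
            "seed": config.sim.seed,
        },
        "protocol": {
            "pulse_width_ms": config.pulse_width,
            "ees_amplitude_v": config.ees_amplitude,
            "sensory_amplitude_v": config.sensory_amplitude,
            "bootstrap_amplitude_v": config.bootstrap_amplitude,
        },
        "lif": {
            "threshold_v": config.lif.threshold,
            "tau_m_ms": config.lif.tau_m,
            "reset_v": config.lif.v_reset,
            "refractory_ms": config.lif.t_ref,
            "pulse_amplitude_v": config.lif.pulse_amplitude,
            "pulse_width_ms": config.lif.pulse_width,
        },
        "motor": {
            "threshold_v": config.mn_lif.threshold,
            "tau_m_ms": config.mn_lif.tau_m,
            "reset_v": config.mn_lif.v_reset,
            "refractory_ms": config.mn_lif.t_ref,
        },
        "device": {
            "r_min_kohm": config.r_min,
            "r_max_kohm": config.r_max,
            "anchors": [list(a) for a in config.transfer.anchors],
        },
        "stdp": {
            "a_plus": config.stdp.a_plus,
            "a_minus": config.stdp.a_minus,
            "tau_plus_ms": config.stdp.tau_plus,
            "tau_minus_ms": config.stdp.tau_minus,
            "window_ms": config.stdp.window,
            "pwm_gain": config.stdp.pwm_gain,
        },
        "circuit": {
            "mode": config.mode,
            "bootstrap": config.bootstrap,
            "ln_resistance_kohm": config.ln_resistance,
            "fixed_pink_kohm": config.fixed_pink_resistance,
            "initial_r_kohm": dict(config.initial_resistance),
            "delays_ms": dict(config.delays),
        },
    }


def load_config(path: str | Path) -> CircuitConfig:
    """Load and validate a YAML (or JSON) config file; defaults filled in."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return config_from_dict(data or {})


def save_config(config: CircuitConfig, path: str | Path) -> None:
    """Write a config to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
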