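"""Circuit-level behavior: trials, learning loop, calibration, controls."""
from dataclasses import replace

import numpy as np
import pytest

from memcpg import (
    CalibrationError,
    CircuitConfig,
    calibrate,
    calibrate_delays,
    classify_responses,
    run_control_resistor,
    run_learning,
    run_trial,
)


class TestSpikeCountRegimes:
    @pytest.mark.parametrize("resistance, expected", [(170.0, 0), (60.0, 1), (30.0, 2)])
    def test_green_spike_count_per_resistance(self, config, resistance, expected):
        result = run_trial(config, {"green": resistance}, bootstrap=False)
        assert result.spikes["green"].size == expected

    def test_single_spike_sits_at_the_200ms_coincidence(self, config):
        result = run_trial(config, {"green": 60.0}, bootstrap=False)
        (t,) = result.spikes["green"]
        assert 200.0 <= t <= 201.0 + config.sim.dt

    def test_spike_count_non_increasing_in_resistance(self, config):
        counts = [
            run_trial(config, {"green": r}, bootstrap=False, record_traces=False)
            .spikes["green"].size
            for r in np.linspace(20.0, 200.0, 61)
        ]
        assert np.all(np.diff(counts) <= 0)

    def test_membrane_trace_invariants_hold_on_all_neurons(self, config):
        result = run_trial(config, {"green": 30.0}, bootstrap=False)
        for name, trace in result.traces.items():
            trace.check_invariants(config.mn_lif if name == "mn" else config.lif)


class TestDeterminism:
    def test_identical_configs_give_identical_trials(self, config):
        a = run_trial(config, {"green": 30.0})
        b = run_trial(config, {"green": 30.0})
        assert np.array_equal(a.mn_spikes, b.mn_spikes)
        for name in a.spikes:
            assert np.array_equal(a.spikes[name], b.spikes[name])
            assert np.array_equal(a.traces[name].potential, b.traces[name].potential)

    def test_identical_configs_give_identical_learning_runs(self):
        cfg = CircuitConfig(mode="single")
        r1 = run_learning(cfg, n_trials=20)
        r2 = run_learning(cfg, n_trials=20)
        assert np.array_equal(r1.trajectory["green"], r2.trajectory["green"])


class TestLearning:
    def test_bootstrap_escapes_zero_output_deadlock(self):
        # at the resistance ceiling the 200+20 Hz sum never reaches threshold:
        # no spikes -> no pairings -> no learning without the 100 Hz drive
        cfg = CircuitConfig(mode="single", initial_resistance={"pink": 200.0, "green": 200.0})
        frozen = run_learning(cfg, n_trials=30, bootstrap=False)
        assert np.all(frozen.trajectory["green"] == 200.0)
        learning = run_learning(cfg, n_trials=30, bootstrap=True)
        assert learning.final_states["green"].resistance < 200.0

    def test_trajectory_non_increasing_and_bounded(self, dual_learning_run):
        for traj in dual_learning_run.trajectory.values():
            assert np.all(np.diff(traj) <= 0)
            assert np.all((traj >= 20.0) & (traj <= 200.0))

    def test_floor_is_absorbing(self):
        cfg = CircuitConfig(mode="single", initial_resistance={"pink": 20.0, "green": 20.0})
        run = run_learning(cfg, n_trials=10)
        assert np.all(run.trajectory["green"] == 20.0)

    def test_fixed_weight_neurons_identical_across_trials(self):
        cfg = CircuitConfig(mode="single", initial_resistance={"pink": 170.0, "green": 170.0})
        run = run_learning(cfg, n_trials=15, record_traces=False)
        blue0 = run.trials[0].spikes["blue"]
        yellow0 = run.trials[0].spikes["yellow"]
        for trial in run.trials[1:]:
            assert np.array_equal(trial.spikes["blue"], blue0)
            assert np.array_equal(trial.spikes["yellow"], yellow0)

    def test_no_output_spikes_means_no_update(self, config):
        cfg = CircuitConfig(mode="single", initial_resistance={"pink": 170.0, "green": 170.0})
        run = run_learning(cfg, n_trials=1, bootstrap=False)
        assert run.trajectory["green"].tolist() == [170.0, 170.0]

    def test_degenerate_trial_count_rejected(self):
        with pytest.raises(ValueError):
            run_learning(CircuitConfig(), n_trials=0)


class TestControlResistor:
    def test_matches_memristive_trial_at_equal_resistance(self, config):
        mem = run_trial(config, {"green": 25.0}, bootstrap=False)
        ctl = run_control_resistor(
            config, 25.0, resistances={"green": 25.0}, bootstrap=False
        )
        assert np.array_equal(mem.mn_spikes, ctl.mn_spikes)
        assert np.array_equal(mem.spikes["green"], ctl.spikes["green"])

    def test_one_kohm_produces_extra_early_latency_responses(self, tuned_dual_config):
        """At 1 kOhm a single 200 Hz pulse reaches threshold, so green fires
        off-coincidence and MN responses leak out of the late band."""
        cfg = tuned_dual_config
        ees = cfg.build_protocol().ees.onset_times
        mem = run_trial(cfg, {"pink": 25.0, "green": 30.0}, bootstrap=False)
        ctl = run_control_resistor(
            cfg, 1.0, resistances={"pink": 25.0}, bootstrap=False
        )
        assert ctl.spikes["green"].size > mem.spikes["green"].size

        def green_early(result):
            cls, _ = classify_responses(result.mn_spikes, ees, sources=result.mn_sources)
            return sum(1 for c in cls if c.source == "green" and c.label == "early")

        assert green_early(ctl) > green_early(mem)

    def test_degenerate_resistance_rejected(self, config):
        with pytest.raises(ValueError):
            run_control_resistor(config, 0.0)


class TestCalibration:
    def test_default_grid_is_feasible_and_replays(self, config):
        result = calibrate(config)
        tuned = replace(config, lif=result.lif, ees_amplitude=result.ees_amplitude)
        counts = {
            r: run_trial(tuned, {"green": r}, bootstrap=False, record_traces=False)
            .spikes["green"].size
            for r in (170.0, 60.0, 30.0)
        }
        assert counts == {170.0: 0, 60.0: 1, 30.0: 2}

    def test_contradictory_constraints_rejected(self, config):
        with pytest.raises(CalibrationError):
            calibrate(config, constraints=((60.0, 1), (60.0, 2)))

    def test_infeasible_grid_raises(self, config):
        with pytest.raises(CalibrationError):
            calibrate(config, taus=(1000.0,), ees_amplitudes=(0.01,), thresholds=(50.0,))

    def test_delay_compensation_hits_latency_targets(self, tuned_dual_config):
        cfg = tuned_dual_config
        post = run_trial(cfg, {"pink": 20.0, "green": 20.0}, bootstrap=False)
        ees = cfg.build_protocol().ees.onset_times
        cls, orphans = classify_responses(post.mn_spikes, ees, sources=post.mn_sources)
        assert not orphans
        by_source = {}
        for c in cls:
            by_source.setdefault(c.source, []).append(c.latency)
        targets = {"blue": 10.0, "yellow": 20.0, "pink": 32.0, "green": 38.0}
        for name, target in targets.items():
            assert all(abs(lat - target) <= 0.5 for lat in by_source[name])
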