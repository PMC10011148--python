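"""Pulse-train generation: half-open window arithmetic and rasterization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memcpg.protocol import (
    BOOTSTRAP_WINDOWS_MS,
    MEMRISTIVE_NEURONS,
    PATTERN_NEURONS,
    SENSORY_WINDOWS_MS,
    PulseTrain,
    build_default_protocol,
    detect_onsets,
    generate_pulse_train,
    rasterize,
)


def _brute_force_count(frequency, start, end):
    """Enumerate pulse onsets one by one (independent oracle)."""
    period = 1000.0 / frequency
    t, count = start, 0
    while t < end - 1e-9:
        count += 1
        t = start + count * period
    return count


@pytest.mark.parametrize(
    "frequency, window, expected_onsets",
    [
        (200.0, (0.0, 100.0), np.arange(0.0, 100.0, 5.0)),
        (20.0, (0.0, 250.0), np.arange(0.0, 250.0, 50.0)),
        (100.0, (100.0, 200.0), np.arange(100.0, 200.0, 10.0)),
        (200.0, (150.0, 250.0), np.arange(150.0, 250.0, 5.0)),
    ],
)
def test_pulse_onsets_half_open_window(frequency, window, expected_onsets):
    train = generate_pulse_train(frequency, window, amplitude=1.0)
    assert np.allclose(train.onset_times, expected_onsets)


@given(
    frequency=st.floats(1.0, 500.0),
    start=st.floats(0.0, 200.0),
    length=st.floats(1.0, 250.0),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_pulse_count_matches_enumeration_oracle(frequency, start, length):
    end = min(start + length, 250.0)
    if end <= start:
        return
    train = generate_pulse_train(frequency, (start, end), amplitude=1.0)
    assert train.n_pulses == _brute_force_count(frequency, start, end)


@pytest.mark.parametrize(
    "frequency, window",
    [(200.0, (-1.0, 50.0)), (200.0, (0.0, 300.0)), (200.0, (50.0, 50.0)),
     (0.0, (0.0, 100.0)), (-5.0, (0.0, 100.0))],
)
def test_invalid_window_or_frequency_rejected(frequency, window):
    with pytest.raises(ValueError):
        generate_pulse_train(frequency, window, amplitude=1.0)


def test_pulse_train_invariants_enforced():
    with pytest.raises(ValueError):
        PulseTrain((10.0, 5.0), width=1.0, amplitude=1.0)
    with pytest.raises(ValueError):
        PulseTrain((0.0,), width=0.0, amplitude=1.0)
    with pytest.raises(ValueError):
        PulseTrain((0.0,), width=1.0, amplitude=-0.1)


class TestDefaultProtocol:
    def test_window_layout_and_sharing(self):
        proto = build_default_protocol()
        assert set(proto.channels) == set(PATTERN_NEURONS) | {"mn"}
        # staggered 200 Hz windows, heel to toe
        for name in PATTERN_NEURONS:
            onsets = proto.channels[name]["sensory"].onset_times
            lo, hi = SENSORY_WINDOWS_MS[name]
            assert onsets[0] == lo and onsets[-1] == hi - 5.0
            assert len(onsets) == 20
        # the EES train is one shared object across all five neurons
        assert proto.ees.onset_times == tuple(np.arange(0.0, 250.0, 50.0))
        for name in proto.channels:
            assert proto.channels[name]["ees"] == proto.ees
        # bootstrap only on the memristive neurons
        for name in PATTERN_NEURONS:
            assert ("bootstrap" in proto.channels[name]) == (name in MEMRISTIVE_NEURONS)
        boot = proto.channels["pink"]["bootstrap"].onset_times
        assert boot == tuple(np.arange(*BOOTSTRAP_WINDOWS_MS["pink"], 10.0))

    def test_degenerate_trial_length_rejected(self):
        with pytest.raises(ValueError):
            build_default_protocol(trial_length=0.0)

    def test_generation_is_deterministic(self):
        a, b = build_default_protocol(), build_default_protocol()
        for name in a.channels:
            assert a.channels[name] == b.channels[name]


class TestRasterize:
    def test_empty_train_is_all_zero(self):
        train = PulseTrain((), width=1.0, amplitude=1.0)
        assert not rasterize(train, 0.1, 250.0).any()

    def test_single_pulse_shape(self):
        train = PulseTrain((10.0,), width=1.0, amplitude=1.0)
        samples = rasterize(train, 0.1, 250.0)
        assert samples[100:110].tolist() == [1.0] * 10
        assert samples.sum() == 10.0

    def test_integral_matches_pulse_area(self):
        train = generate_pulse_train(20.0, (0.0, 250.0), amplitude=4.0, width=1.0)
        dt = 0.1
        integral = rasterize(train, dt, 250.0).sum() * dt
        assert abs(integral - train.n_pulses * 4.0 * 1.0) <= dt

    def test_dt_coarser_than_width_rejected(self):
        train = PulseTrain((10.0,), width=1.0, amplitude=1.0)
        with pytest.raises(ValueError):
            rasterize(train, 2.0, 250.0)

    @pytest.mark.parametrize("dt", [0.1, 0.25, 0.5, 1.0])
    def test_onset_detection_roundtrip(self, dt):
        proto = build_default_protocol()
        for name in PATTERN_NEURONS:
            train = proto.channels[name]["sensory"]
            recovered = detect_onsets(rasterize(train, dt, 250.0), dt)
            assert np.allclose(recovered, train.onset_times)
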