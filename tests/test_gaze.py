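"""Saccade/blink detection and slow-phase displacement construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oknpupil.gaze import (
    build_clean_displacement,
    detect_blinks,
    detect_saccades,
    fill_blink_buffers,
)
from oknpupil.types import DisplacementTrace, IntervalSet, RecordingTrace


def make_trace(x, y=None, pupil=None, fs=1000.0, valid=None):
    n = len(x)
    t = np.arange(n) / fs
    y = np.zeros(n) if y is None else y
    pupil = np.full(n, 4.5) if pupil is None else pupil
    valid = np.ones(n, dtype=bool) if valid is None else valid
    return RecordingTrace(t, x.copy(), y.copy(), x.copy(), y.copy(), pupil, valid)


def drift_with_pulse(fs=1000.0, dur=2.0, pulse_at=1.0, pulse_ms=30.0, pulse_speed=300.0):
    n = int(dur * fs)
    t = np.arange(n) / fs
    x = 2.0 * t  # constant 2 deg/s drift
    in_pulse = (t >= pulse_at) & (t < pulse_at + pulse_ms / 1000.0)
    x = x + pulse_speed * np.cumsum(in_pulse) / fs
    return t, x


class TestDetectSaccades:
    def test_constant_velocity_drift_has_no_saccades(self):
        t = np.arange(2000) / 1000.0
        trace = make_trace(2.0 * t)
        assert len(detect_saccades(trace)) == 0

    def test_single_velocity_pulse_yields_one_interval(self):
        _, x = drift_with_pulse()
        trace = make_trace(x)
        sacc = detect_saccades(trace)
        assert len(sacc) == 1
        s, e, label = next(iter(sacc))
        assert label == "saccade"
        # the detected interval covers the 30-ms pulse at 1.0 s
        assert s <= 1.0 + 0.005 and e >= 1.028

    def test_monocular_pulse_still_reported(self):
        t, x = drift_with_pulse()
        trace = make_trace(2.0 * t)
        trace.xL = x  # pulse in the left eye only
        sacc = detect_saccades(trace)
        assert len(sacc) == 1

    @pytest.mark.parametrize("offset", [-7.3, 0.0, 12.5])
    def test_invariant_to_constant_gaze_offset(self, offset):
        _, x = drift_with_pulse()
        base = detect_saccades(make_trace(x))
        shifted = detect_saccades(make_trace(x + offset))
        np.testing.assert_allclose(base.starts, shifted.starts)
        np.testing.assert_allclose(base.ends, shifted.ends)

    def test_all_invalid_trace_warns_and_returns_empty(self):
        x = np.full(100, np.nan)
        trace = make_trace(x, valid=np.zeros(100, dtype=bool))
        with pytest.warns(UserWarning):
            assert len(detect_saccades(trace)) == 0


def eyelid_ramp(fs=1000.0, dur=2.0, onset=0.8, drop=2.0, down_ms=50.0, closed_ms=100.0, up_ms=100.0):
    n = int(dur * fs)
    t = np.arange(n) / fs
    pupil = np.full(n, 4.5)
    down = (t >= onset) & (t < onset + down_ms / 1000.0)
    closed = (t >= onset + down_ms / 1000.0) & (
        t < onset + (down_ms + closed_ms) / 1000.0
    )
    up_start = onset + (down_ms + closed_ms) / 1000.0
    up = (t >= up_start) & (t < up_start + up_ms / 1000.0)
    pupil[down] -= drop * (t[down] - onset) / (down_ms / 1000.0)
    pupil[closed] -= drop
    pupil[up] -= drop * (1 - (t[up] - up_start) / (up_ms / 1000.0))
    return t, pupil


class TestDetectBlinks:
    def test_constant_pupil_yields_empty_set(self):
        trace = make_trace(np.zeros(1000))
        assert len(detect_blinks(trace)) == 0

    def test_eyelid_ramp_detected_as_single_blink(self):
        # 2-mm drop over 50 ms (40 mm/s) far exceeds the 10 mm/s threshold
        t, pupil = eyelid_ramp()
        trace = make_trace(np.zeros(len(t)), pupil=pupil)
        blinks = detect_blinks(trace).with_label("blink")
        assert len(blinks) == 1
        s, e, _ = next(iter(blinks))
        assert s == pytest.approx(0.8, abs=0.03)
        assert e >= 0.95 - 0.03  # extends into the recovery ramp

    def test_nearby_artifacts_merged(self):
        t, p1 = eyelid_ramp(onset=0.5)
        _, p2 = eyelid_ramp(onset=0.77)  # 20 ms after the first recovery ends
        pupil = np.minimum(p1, p2)
        trace = make_trace(np.zeros(len(t)), pupil=pupil)
        blinks = detect_blinks(trace, merge_gap_ms=50.0).with_label("blink")
        assert len(blinks) == 1

    def test_invalid_runs_labeled_missing(self):
        n = 1000
        valid = np.ones(n, dtype=bool)
        valid[300:400] = False
        pupil = np.full(n, 4.5)
        pupil[~valid] = np.nan
        trace = make_trace(np.zeros(n), pupil=pupil, valid=valid)
        missing = detect_blinks(trace).with_label("missing")
        assert len(missing) == 1
        s, e, _ = next(iter(missing))
        assert s == pytest.approx(0.3, abs=1e-6)
        assert e == pytest.approx(0.4, abs=1e-6)


class TestCleanDisplacement:
    def test_no_artifacts_identity_up_to_offset(self):
        x = np.cumsum(np.random.default_rng(0).normal(0, 0.01, 500))
        trace = make_trace(x + 3.0)
        disp = build_clean_displacement(trace, IntervalSet.empty())
        np.testing.assert_allclose(disp.x, x - x[0], atol=1e-12)

    def test_sawtooth_with_flagged_resets_is_monotone(self):
        # 2 deg/s slow phase, instantaneous resets every second, flagged
        fs = 1000.0
        n = 4000
        t = np.arange(n) / fs
        x = 2.0 * (t % 1.0)
        trace = make_trace(x)
        reset_times = np.array([1.0, 2.0, 3.0])
        artifacts = IntervalSet(
            reset_times - 1.5 / fs,
            reset_times + 0.5 / fs,
            np.full(3, "saccade", dtype=object),
        )
        disp = build_clean_displacement(trace, artifacts)
        dx = np.diff(disp.x)
        assert np.all(dx >= -1e-12)
        # slope stays 2 deg/s through the slow phases: oracle = sum of
        # slow-phase increments only
        expected_total = 2.0 * (t[-1] - 3 * 2.0 / fs)
        assert disp.x[-1] == pytest.approx(expected_total, rel=0.01)

    def test_blink_increments_contribute_zero(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = 2.0 * t
        trace = make_trace(x)
        blink = IntervalSet(
            np.array([0.5]), np.array([0.7]), np.array(["blink"], dtype=object)
        )
        disp = build_clean_displacement(trace, blink)
        in_blink = (t >= 0.5) & (t < 0.7)
        assert np.all(np.diff(disp.x)[in_blink[1:]] == 0.0)
        lost = 2.0 * 0.2  # displacement during the zeroed blink
        assert disp.x[-1] == pytest.approx(x[-1] - x[0] - lost, abs=0.02)


class TestFillBlinkBuffers:
    def test_no_blinks_is_identity(self):
        t = np.arange(1000) / 1000.0
        disp = DisplacementTrace(t, 2.0 * t, np.zeros_like(t))
        out = fill_blink_buffers(disp, IntervalSet.empty())
        np.testing.assert_allclose(out.x, disp.x)

    def test_constant_velocity_bridged_through_blink(self):
        # uniform 2 deg/s with the blink's increments zeroed out: the filled
        # buffer must continue at 2 deg/s and restore the lost displacement
        fs = 1000.0
        t = np.arange(4000) / fs
        x = 2.0 * t
        blink = IntervalSet(
            np.array([1.5]), np.array([1.8]), np.array(["blink"], dtype=object)
        )
        dx = np.full(len(t), 2.0 / fs)
        dx[0] = 0.0
        dx[blink.mask(t)] = 0.0
        disp = DisplacementTrace(t, np.cumsum(dx), np.zeros_like(t))
        filled = fill_blink_buffers(disp, blink)
        np.testing.assert_allclose(filled.x[-1], x[-1] - x[0], rtol=1e-3)
        inc = np.diff(filled.x)
        buffer = (t >= 1.5 - 0.25) & (t < 1.8 + 0.4)
        np.testing.assert_allclose(inc[buffer[1:]], 2.0 / fs, rtol=1e-6)

    def test_buffer_extends_250ms_before_and_400ms_after(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        disp = DisplacementTrace(t, np.zeros_like(t), np.zeros_like(t))
        # mark the buffer by replacing zero increments with a nonzero flank mean
        x = t.copy()  # increments 1/fs everywhere
        disp = DisplacementTrace(t, x, np.zeros_like(t))
        blink = IntervalSet(
            np.array([2.0]), np.array([2.1]), np.array(["blink"], dtype=object)
        )
        filled = fill_blink_buffers(disp, blink)
        # identical increments in and out: output equals input, but the
        # replaced span is exactly blink + 0.650 s
        inc_in = np.diff(disp.x)
        inc_out = np.diff(filled.x)
        changed_possible = (t >= 2.0 - 0.25) & (t < 2.1 + 0.4)
        outside = ~changed_possible
        np.testing.assert_allclose(inc_out[outside[1:]], inc_in[outside[1:]])
        span = changed_possible.sum() / fs
        assert span == pytest.approx(0.1 + 0.65, abs=2.0 / fs)


@given(st.floats(min_value=-20, max_value=20))
def test_saccade_detection_offset_invariance_property(offset):
    _, x = drift_with_pulse(fs=500.0, dur=1.6, pulse_at=0.8)
    base = detect_saccades(make_trace(x, fs=500.0))
    shifted = detect_saccades(make_trace(x + offset, fs=500.0))
    assert len(base) == len(shifted)
    np.testing.assert_allclose(base.starts, shifted.starts)
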