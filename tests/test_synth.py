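"""Generator-level checks: dominance statistics, stimulus timing, pupil
superposition, report delays, and whole-session reproducibility."""

import numpy as np
import pytest
from dataclasses import replace

from oknpupil.gaze import detect_saccades
from oknpupil.synth import (
    KernelSpec,
    SimConfig,
    simulate_okn_gaze,
    simulate_percept_sequence,
    simulate_pupil,
    simulate_reports,
    simulate_session,
    simulate_stimulus_events,
)
from oknpupil.types import EventSeries, RecordingTrace


class TestPerceptSequence:
    def test_zero_duration_yields_no_switches(self):
        cfg = SimConfig(seed=1)
        _, switches = simulate_percept_sequence(cfg, duration_s=0.0)
        assert len(switches) == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_percept_sequence(SimConfig(seed=1), duration_s=-1.0)

    def test_same_seed_identical_timeline(self):
        cfg = SimConfig(seed=5)
        t1, s1 = simulate_percept_sequence(cfg)
        t2, s2 = simulate_percept_sequence(cfg)
        np.testing.assert_array_equal(t1.boundaries, t2.boundaries)
        np.testing.assert_array_equal(s1.times, s2.times)
        np.testing.assert_array_equal(s1.directions, s2.directions)

    def test_dominance_durations_match_gamma_mean(self):
        # law-of-large-numbers check over ~1e3 epochs spanning 1e4 s
        cfg = SimConfig(dominance_shape=3.0, dominance_mean_s=10.0, seed=11)
        timeline, _ = simulate_percept_sequence(cfg, duration_s=10_000.0)
        durations = np.diff(timeline.boundaries)[:-1]  # drop truncated last epoch
        assert abs(durations.mean() - 10.0) / 10.0 < 0.02

    def test_directions_strictly_alternate(self):
        cfg = SimConfig(seed=3)
        _, switches = simulate_percept_sequence(cfg, duration_s=600.0)
        dirs = switches.directions
        assert all(a != b for a, b in zip(dirs[:-1], dirs[1:]))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("duration_s", -1.0),
            ("dominance_mean_s", 0.0),
            ("report_miss_prob", 1.5),
            ("sample_rate_hz", 100.0),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = replace(SimConfig(), **{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestStimulusEvents:
    def test_element_trajectory_has_six_second_period(self, rng):
        _, traj = simulate_stimulus_events(SimConfig(seed=2), rng, duration_s=60.0)
        t = np.linspace(0.0, 30.0, 301)
        x1, _ = traj.position(t)
        x2, _ = traj.position(t + 6.0)
        np.testing.assert_allclose(x1, x2, atol=1e-12)

    def test_element_replaced_at_500ms_lifetime(self, rng):
        _, traj = simulate_stimulus_events(SimConfig(seed=2), rng, duration_s=60.0)
        reps = traj.replacement_times(20.0)
        np.testing.assert_allclose(np.diff(reps), 0.5)
        eps = 1e-9
        assert traj.age(reps[0] - eps) == pytest.approx(0.5, abs=1e-6)

    def test_mean_inversion_interval_near_five_seconds(self, rng):
        inv, _ = simulate_stimulus_events(
            SimConfig(seed=2), rng, duration_s=20_000.0
        )
        intervals = np.diff(inv.times)
        assert abs(intervals.mean() - 5.0) / 5.0 < 0.05


class TestOknGaze:
    def test_gaze_stays_within_reset_bound(self, small_cfg, rng):
        percepts, _ = simulate_percept_sequence(small_cfg, rng)
        gz = simulate_okn_gaze(percepts, small_cfg, rng)
        travel = (
            small_cfg.slow_phase_speed_degps * small_cfg.saccade_duration_ms / 1000.0
        )
        assert np.nanmax(np.abs(gz.x_true)) <= small_cfg.reset_eccentricity_deg + travel + 1e-9

    def test_injected_saccades_recovered_by_detector(self, small_cfg, rng):
        percepts, _ = simulate_percept_sequence(small_cfg, rng)
        gz = simulate_okn_gaze(percepts, small_cfg, rng)
        trace = RecordingTrace(
            gz.t, gz.xL, gz.yL, gz.xR, gz.yR, np.full(len(gz.t), 4.5), gz.valid
        )
        detected = detect_saccades(trace)
        hits = 0
        for s, e, _ in gz.saccades:
            overlap = (detected.starts < e) & (detected.ends > s)
            hits += bool(overlap.any())
        assert hits / len(gz.saccades) >= 0.95

    def test_percept_gap_rejected(self, small_cfg, rng):
        percepts, _ = simulate_percept_sequence(small_cfg, rng)
        percepts.boundaries = percepts.boundaries + 1.0  # timeline no longer at 0
        with pytest.raises(ValueError):
            simulate_okn_gaze(percepts, small_cfg, rng)


class TestPupil:
    def test_no_events_no_noise_is_constant_baseline(self, small_cfg, rng):
        p = simulate_pupil({}, small_cfg, rng, noise=False, drift=False)
        np.testing.assert_allclose(p, small_cfg.baseline_pupil_mm)

    def test_single_event_equals_shifted_kernel(self, small_cfg, rng):
        spec = KernelSpec(0.3, 1.5, 4.0)
        p = simulate_pupil(
            {"okn_switch": np.array([10.0])},
            small_cfg,
            rng,
            noise=False,
            drift=False,
            kernels={"okn_switch": spec},
        )
        t = small_cfg.time_grid()
        expected = spec.evaluate(t - 10.0)
        expected[t - 10.0 > 6.0] = 0.0  # kernels live on the -2..+6 s window
        np.testing.assert_allclose(
            p - small_cfg.baseline_pupil_mm, expected, atol=1e-12
        )

    def test_overlapping_events_superpose(self, small_cfg, rng):
        # independent brute-force superposition oracle
        spec = KernelSpec(0.25, 1.75, 5.0)
        times = np.array([8.0, 9.2])
        p = simulate_pupil(
            {"okn_switch": times},
            small_cfg,
            rng,
            noise=False,
            drift=False,
            kernels={"okn_switch": spec},
        )
        t = small_cfg.time_grid()
        oracle = np.full(len(t), small_cfg.baseline_pupil_mm)
        for ev in times:
            k = spec.evaluate(t - ev)
            k[t - ev > 6.0] = 0.0  # kernel support ends at +6 s
            oracle = oracle + k
        np.testing.assert_allclose(p, oracle, atol=1e-12)

    def test_kernel_longer_than_trial_rejected(self, rng):
        cfg = SimConfig(duration_s=4.0, seed=0)
        with pytest.raises(ValueError):
            simulate_pupil({}, cfg, rng)


class TestReports:
    def _switches(self, n, spacing=4.0):
        times = spacing * (1 + np.arange(n))
        dirs = np.empty(n, dtype=object)
        dirs[0::2] = "right"
        dirs[1::2] = "left"
        return EventSeries(
            times, np.full(n, "okn_switch", dtype=object), dirs
        )

    def test_zero_delay_zero_miss_identity(self, rng):
        cfg = SimConfig(
            report_delay_mean_s=0.0,
            report_delay_sd_s=0.0,
            report_miss_prob=0.0,
            seed=0,
        )
        sw = self._switches(10)
        presses = simulate_reports(sw, cfg, rng, duration_s=60.0)
        np.testing.assert_allclose(presses.times, sw.times)
        np.testing.assert_array_equal(presses.directions, sw.directions)

    def test_miss_probability_binomial(self, rng):
        cfg = SimConfig(report_miss_prob=0.3, seed=0)
        sw = self._switches(1000)
        presses = simulate_reports(sw, cfg, rng, duration_s=5000.0)
        # 700 expected, binomial sd ~14.5; allow ~3.5 sd
        assert abs(len(presses) - 700) < 50

    def test_delay_mean_sets_press_lag(self, rng):
        cfg = SimConfig(seed=0)  # default delay mean 1.0 s
        sw = self._switches(500)
        presses = simulate_reports(sw, cfg, rng, duration_s=2500.0)
        lags = []
        for pt in presses.times:
            lags.append(sw.times[np.argmin(np.abs(sw.times - pt))] - pt)
        assert -1.5 < np.mean(lags) < -0.75


class TestSession:
    def test_fixed_seed_reproduces_session(self):
        cfg = SimConfig(duration_s=30.0, n_trials=1, sample_rate_hz=500.0, seed=21)
        a = simulate_session(cfg)
        b = simulate_session(cfg)
        for cond in a.conditions:
            ta, tb = a.conditions[cond][0], b.conditions[cond][0]
            np.testing.assert_array_equal(ta.trace.pupil, tb.trace.pupil)
            np.testing.assert_array_equal(ta.trace.xL, tb.trace.xL)
            assert ta.events.to_frame().equals(tb.events.to_frame())

    def test_ground_truth_events_appear_once_in_event_stream(self):
        cfg = SimConfig(duration_s=60.0, n_trials=1, sample_rate_hz=500.0, seed=8)
        sess = simulate_session(cfg)
        for cond, trials in sess.conditions.items():
            tr = trials[0]
            inv = tr.events.of_type("inversion")
            np.testing.assert_array_equal(
                np.sort(inv.times), np.sort(tr.truth.inversion_times_s)
            )
            presses = tr.events.of_type("key_press")
            np.testing.assert_array_equal(
                np.sort(presses.times), np.sort(tr.truth.report_times_s)
            )
            blinks = tr.events.of_type("blink_onset")
            assert len(blinks) == len(tr.truth.blink_intervals)

    def test_switch_relevant_kernel_peaks_1p5_to_2s(self):
        cfg = SimConfig()
        grid = np.linspace(-2.0, 6.0, 801)
        kernel = cfg.kernels["switch_relevant"]["okn_switch"].evaluate(grid)
        peak_t = grid[np.argmax(kernel)]
        assert 1.5 <= peak_t <= 2.0
        assert kernel[np.argmax(kernel)] > 0
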