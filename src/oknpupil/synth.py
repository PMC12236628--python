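"""Ground-truth session simulator for the no-report bistable perception pipeline.

Emulates an observer viewing an ambiguous structure-from-motion sphere:
perceptual dominance alternates with gamma-distributed durations, gaze shows
optokinetic nystagmus (slow phases following the perceived front surface,
fast-phase resets), the pupil trace is a linear superposition of event-locked
kernels on a drifting baseline, triangle inversions occur as a Poisson stream,
and key-press reports lag the true switches.  Every stage exposes its ground
truth so downstream detectors and estimators can be validated quantitatively.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so sessions are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import EventSeries, IntervalSet, RecordingTrace

PERI_WINDOW = (-2.0, 6.0)  # seconds around an event, used for true kernels


@dataclass(frozen=True)
class KernelSpec:
    """Event-locked pupil impulse response: a gamma-density bump.

    ``amplitude_mm`` is the (signed) peak value, ``peak_s`` the post-event
    latency of the peak, ``shape`` the gamma shape parameter (> 1; larger is
    more symmetric).  The kernel is zero for negative lags.
    """

    amplitude_mm: float
    peak_s: float = 1.75
    shape: float = 5.0

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        if self.shape <= 1:
            raise ValueError("kernel shape must exceed 1")
        if self.peak_s <= 0:
            raise ValueError("kernel peak latency must be positive")
        theta = self.peak_s / (self.shape - 1.0)
        out = np.zeros_like(tau)
        pos = tau > 0
        tp = tau[pos]
        # gamma density normalized to unit peak at tau == peak_s
        out[pos] = (tp / self.peak_s) ** (self.shape - 1.0) * np.exp(
            -(tp - self.peak_s) / theta
        )
        return self.amplitude_mm * out


def _default_kernels() -> dict[str, dict[str, KernelSpec]]:
    # Task-relevant events dilate the pupil (peak 1.5-2 s after the event);
    # ignored perceptual switches constrict it; ignored inversions do nothing.
    return {
        "switch_relevant": {
            "okn_switch": KernelSpec(+0.20, 1.75, 5.0),
            "inversion": KernelSpec(0.0, 1.75, 5.0),
            "blink": KernelSpec(+0.15, 1.0, 5.0),
        },
        "inversion_relevant": {
            "okn_switch": KernelSpec(-0.15, 2.0, 5.0),
            "inversion": KernelSpec(+0.20, 1.75, 5.0),
            "blink": KernelSpec(+0.15, 1.0, 5.0),
        },
    }


@dataclass
class SimConfig:
    """All tunable parameters of the generative model (one trial template).

    Stimulus constants default to the experiment's printed values: the sphere
    rotates once per 6 s, elements live 500 ms, triangle inversions arrive on
    average every 5 s, and recording runs at 1000 Hz.
    """

    duration_s: float = 120.0
    n_trials: int = 4
    sample_rate_hz: float = 1000.0
    # perceptual dynamics
    dominance_mean_s: float = 10.0
    dominance_shape: float = 3.0
    # OKN kinematics
    slow_phase_speed_degps: float = 2.0
    reset_eccentricity_deg: float = 3.0
    saccade_duration_ms: float = 30.0
    # stimulus
    inversion_mean_interval_s: float = 5.0
    rotation_period_s: float = 6.0
    element_lifetime_ms: float = 500.0
    sphere_radius_deg: float = 3.0
    # pupil generative model
    kernels: dict[str, dict[str, KernelSpec]] = field(default_factory=_default_kernels)
    baseline_pupil_mm: float = 4.5
    drift_amp_mm: float = 0.15
    drift_period_s: float = 40.0
    # blinks
    blink_rate_hz: float = 0.2
    blink_duration_ms: float = 150.0
    blink_drop_mm: float = 2.0
    blink_ramp_down_ms: float = 50.0
    blink_ramp_up_ms: float = 100.0
    # manual reports
    report_delay_mean_s: float = 1.0
    report_delay_sd_s: float = 0.2
    report_miss_prob: float = 0.1
    # noise
    gaze_noise_sd_deg: float = 0.02
    pupil_noise_sd_mm: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "duration_s": self.duration_s,
            "sample_rate_hz": self.sample_rate_hz,
            "dominance_mean_s": self.dominance_mean_s,
            "dominance_shape": self.dominance_shape,
            "slow_phase_speed_degps": self.slow_phase_speed_degps,
            "reset_eccentricity_deg": self.reset_eccentricity_deg,
            "saccade_duration_ms": self.saccade_duration_ms,
            "inversion_mean_interval_s": self.inversion_mean_interval_s,
            "rotation_period_s": self.rotation_period_s,
            "element_lifetime_ms": self.element_lifetime_ms,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not 0.0 <= self.report_miss_prob <= 1.0:
            raise ValueError("report_miss_prob must lie in [0, 1]")
        if self.sample_rate_hz < 250:
            raise ValueError("sample_rate_hz must be >= 250")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sample_rate_hz))
        return np.arange(n) / self.sample_rate_hz


@dataclass
class PerceptTimeline:
    """Alternating left/right dominance epochs covering [0, duration)."""

    boundaries: np.ndarray  # epoch edges, boundaries[0] == 0, last == duration
    directions: np.ndarray  # per-epoch labels, len == len(boundaries) - 1
    duration: float

    def direction_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.boundaries, np.asarray(t, float), side="right") - 1,
            0,
            len(self.directions) - 1,
        )
        return self.directions[idx]

    def switches(self) -> EventSeries:
        """Epoch boundaries interior to the trial, labeled with the new percept."""
        times = self.boundaries[1:-1]
        dirs = self.directions[1:]
        return EventSeries(
            times,
            np.full(len(times), "okn_switch", dtype=object),
            np.asarray(dirs, dtype=object),
        )


@dataclass(frozen=True)
class ElementTrajectory:
    """On-screen path of one sphere element plus its replacement schedule.

    The horizontal position traces the projected great circle of the rotating
    sphere (sinusoidal, period ``period_s``); replacement relocates the
    element to a new path every ``lifetime_s``.
    """

    radius_deg: float
    period_s: float
    lifetime_s: float
    phase: float = 0.0
    y_deg: float = 0.0
    start_age_s: float = 0.0

    def position(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        x = self.radius_deg * np.sin(2.0 * np.pi * t / self.period_s + self.phase)
        return x, np.full_like(t, self.y_deg)

    def age(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) + self.start_age_s) % self.lifetime_s

    def replacement_times(self, duration_s: float) -> np.ndarray:
        first = self.lifetime_s - self.start_age_s
        return np.arange(first, duration_s, self.lifetime_s)


@dataclass
class GroundTruth:
    """Per-trial generative record used for parameter-recovery validation."""

    switch_times_s: np.ndarray
    switch_directions: np.ndarray
    inversion_times_s: np.ndarray
    blink_intervals: IntervalSet
    saccade_intervals: IntervalSet
    report_times_s: np.ndarray
    report_keys: np.ndarray
    kernel_grid: np.ndarray = None  # type: ignore[assignment]
    true_kernels: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class TrialData:
    trace: RecordingTrace
    events: EventSeries  # observed streams: key_press, inversion, blink_onset
    truth: GroundTruth


@dataclass
class Session:
    """One observer's full two-condition dataset."""

    config: SimConfig
    conditions: dict[str, list[TrialData]]
    observer: str = "sim"


def _rng_from(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_percept_sequence(
    cfg: SimConfig, rng=None, duration_s: float | None = None
) -> tuple[PerceptTimeline, EventSeries]:
    """Draw alternating dominance epochs with gamma-distributed durations.

    Returns the percept timeline and the switch events (epoch boundaries,
    labeled with the post-switch direction).  ``duration_s == 0`` yields an
    empty switch list.
    """
    cfg_dur = cfg.duration_s if duration_s is None else duration_s
    if cfg_dur < 0:
        raise ValueError("duration must be non-negative")
    rng = _rng_from(cfg.seed if rng is None else rng)
    if cfg_dur == 0:
        timeline = PerceptTimeline(
            np.array([0.0, 0.0]), np.array(["right"], dtype=object), 0.0
        )
        return timeline, EventSeries.empty()
    cfg.validate()
    scale = cfg.dominance_mean_s / cfg.dominance_shape
    first = "right" if rng.random() < 0.5 else "left"
    edges = [0.0]
    total = 0.0
    # draw durations in blocks for speed
    while total < cfg_dur:
        block = rng.gamma(cfg.dominance_shape, scale, size=64)
        for d in block:
            total += d
            edges.append(min(total, cfg_dur))
            if total >= cfg_dur:
                break
    boundaries = np.array(edges)
    n_epochs = len(boundaries) - 1
    dirs = np.empty(n_epochs, dtype=object)
    dirs[0::2] = first
    dirs[1::2] = "left" if first == "right" else "right"
    timeline = PerceptTimeline(boundaries, dirs, cfg_dur)
    return timeline, timeline.switches()


def simulate_stimulus_events(
    cfg: SimConfig, rng=None, duration_s: float | None = None
) -> tuple[EventSeries, ElementTrajectory]:
    """Poisson triangle-inversion stream plus one representative element path."""
    cfg.validate()
    dur = cfg.duration_s if duration_s is None else duration_s
    rng = _rng_from(cfg.seed if rng is None else rng)
    # renewal process with exponential intervals: "random moments", mean 5 s
    n_guess = max(8, int(3 * dur / cfg.inversion_mean_interval_s))
    times = np.cumsum(rng.exponential(cfg.inversion_mean_interval_s, size=n_guess))
    while times[-1] < dur:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.exponential(cfg.inversion_mean_interval_s, size=n_guess))]
        )
    times = times[times < dur]
    # triangle orientation toggles up/down at each inversion
    start_up = rng.random() < 0.5
    dirs = np.empty(len(times), dtype=object)
    dirs[0::2] = "down" if start_up else "up"
    dirs[1::2] = "up" if start_up else "down"
    inversions = EventSeries(
        times, np.full(len(times), "inversion", dtype=object), dirs
    )
    traj = ElementTrajectory(
        radius_deg=cfg.sphere_radius_deg,
        period_s=cfg.rotation_period_s,
        lifetime_s=cfg.element_lifetime_ms / 1000.0,
        phase=float(rng.uniform(0, 2 * np.pi)),
        y_deg=float(rng.uniform(-cfg.sphere_radius_deg, cfg.sphere_radius_deg)),
        start_age_s=float(rng.uniform(0, cfg.element_lifetime_ms / 1000.0)),
    )
    return inversions, traj


@dataclass
class GazeSim:
    t: np.ndarray
    x_true: np.ndarray  # noiseless binocular slow-phase + fast-phase path
    xL: np.ndarray
    yL: np.ndarray
    xR: np.ndarray
    yR: np.ndarray
    valid: np.ndarray
    saccades: IntervalSet
    blinks: IntervalSet


def _draw_blinks(cfg: SimConfig, rng: np.random.Generator, duration: float) -> IntervalSet:
    """Non-overlapping blink occlusion intervals (ramps included)."""
    blink_len = (
        cfg.blink_ramp_down_ms + cfg.blink_duration_ms + cfg.blink_ramp_up_ms
    ) / 1000.0
    starts: list[float] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / cfg.blink_rate_hz) if cfg.blink_rate_hz > 0 else np.inf
        if t + blink_len >= duration:
            break
        if starts and t < starts[-1] + blink_len + 0.2:
            continue  # refractory: keep blinks apart
        starts.append(t)
    if not starts:
        return IntervalSet.empty()
    s = np.array(starts)
    return IntervalSet(s, s + blink_len, np.full(len(s), "blink", dtype=object))


def simulate_okn_gaze(
    percepts: PerceptTimeline,
    cfg: SimConfig,
    rng=None,
    blinks: IntervalSet | None = None,
) -> GazeSim:
    """Piecewise-linear OKN path: slow phases at the percept's direction and
    speed, fast-phase resets to center when gaze reaches the eccentricity
    bound.  Both eyes share the slow-phase path and receive independent
    sensor noise; blink intervals blank the gaze signal.
    """
    cfg.validate()
    if percepts.duration <= 0 or len(percepts.directions) == 0:
        raise ValueError("percept timeline must cover a positive duration")
    if not np.isclose(percepts.boundaries[0], 0.0):
        raise ValueError("percept timeline must start at 0 (gap detected)")
    rng = _rng_from(cfg.seed if rng is None else rng)
    dur = percepts.duration
    bound = cfg.reset_eccentricity_deg
    speed = cfg.slow_phase_speed_degps
    sacc = cfg.saccade_duration_ms / 1000.0

    knot_t: list[float] = [0.0]
    knot_x: list[float] = [0.0]
    sac_start: list[float] = []
    cur_t, cur_x = 0.0, 0.0
    i_epoch = 0
    bnd = percepts.boundaries
    n_epochs = len(percepts.directions)
    while cur_t < dur - 1e-12:
        while i_epoch + 1 < n_epochs and bnd[i_epoch + 1] <= cur_t + 1e-12:
            i_epoch += 1
        v = speed if percepts.directions[i_epoch] == "right" else -speed
        epoch_end = bnd[i_epoch + 1] if i_epoch + 1 <= n_epochs else dur
        target = bound if v > 0 else -bound
        hit_t = cur_t + (target - cur_x) / v
        if hit_t <= min(epoch_end, dur):
            knot_t.append(hit_t)
            knot_x.append(target)
            # fast phase: linear return to center
            knot_t.append(min(hit_t + sacc, dur))
            knot_x.append(0.0 if hit_t + sacc <= dur else target * (1 - (dur - hit_t) / sacc))
            sac_start.append(hit_t)
            cur_t, cur_x = hit_t + sacc, 0.0
        else:
            stop = min(epoch_end, dur)
            cur_x = cur_x + v * (stop - cur_t)
            cur_t = stop
            knot_t.append(cur_t)
            knot_x.append(cur_x)
            i_epoch += 1
    t = np.arange(int(round(dur * cfg.sample_rate_hz))) / cfg.sample_rate_hz
    x_true = np.interp(t, np.array(knot_t), np.array(knot_x))

    sac_start_a = np.array(sac_start)
    sac_start_a = sac_start_a[sac_start_a < dur]
    saccades = (
        IntervalSet(
            sac_start_a,
            np.minimum(sac_start_a + sacc, dur),
            np.full(len(sac_start_a), "saccade", dtype=object),
        )
        if len(sac_start_a)
        else IntervalSet.empty()
    )
    if blinks is None:
        blinks = _draw_blinks(cfg, rng, dur)

    noise = cfg.gaze_noise_sd_deg
    xL = x_true + rng.normal(0, noise, len(t))
    xR = x_true + rng.normal(0, noise, len(t))
    yL = rng.normal(0, noise, len(t))
    yR = rng.normal(0, noise, len(t))
    valid = ~blinks.mask(t)
    for arr in (xL, xR, yL, yR):
        arr[~valid] = np.nan
    return GazeSim(t, x_true, xL, yL, xR, yR, valid, saccades, blinks)


def _blink_occlusion(cfg: SimConfig, t: np.ndarray, blinks: IntervalSet) -> np.ndarray:
    """Eyelid artifact: ramp down, plateau, ramp up (positive = size loss)."""
    occ = np.zeros(len(t))
    down = cfg.blink_ramp_down_ms / 1000.0
    up = cfg.blink_ramp_up_ms / 1000.0
    for s, e, _ in blinks:
        m = (t >= s) & (t < e)
        tau = t[m] - s
        seg = np.full(tau.shape, cfg.blink_drop_mm)
        seg[tau < down] = cfg.blink_drop_mm * tau[tau < down] / down
        tail = tau > (e - s) - up
        seg[tail] = cfg.blink_drop_mm * ((e - s) - tau[tail]) / up
        occ[m] = seg
    return occ


def simulate_pupil(
    events: dict[str, np.ndarray],
    cfg: SimConfig,
    rng=None,
    duration_s: float | None = None,
    blinks: IntervalSet | None = None,
    kernels: dict[str, KernelSpec] | None = None,
    noise: bool = True,
    drift: bool = True,
) -> np.ndarray:
    """Pupil trace = baseline + slow drift + Σ event kernels + noise + blink
    artifacts.  ``events`` maps event type to an array of event times;
    ``kernels`` maps the same types to their impulse responses (defaults to
    the switch-relevant set).  Superposition is exact before noise.
    """
    cfg.validate()
    dur = cfg.duration_s if duration_s is None else duration_s
    if PERI_WINDOW[1] > dur:
        raise ValueError("kernel window longer than the trial")
    rng = _rng_from(cfg.seed if rng is None else rng)
    t = np.arange(int(round(dur * cfg.sample_rate_hz))) / cfg.sample_rate_hz
    if kernels is None:
        kernels = cfg.kernels["switch_relevant"]
    pupil = np.full(len(t), cfg.baseline_pupil_mm)
    if drift and cfg.drift_amp_mm > 0:
        phase = rng.uniform(0, 2 * np.pi)
        pupil = pupil + cfg.drift_amp_mm * np.sin(
            2 * np.pi * t / cfg.drift_period_s + phase
        )
    # event-kernel superposition, added sample-aligned for exactness
    kern_len = int(round(PERI_WINDOW[1] * cfg.sample_rate_hz))
    tau = np.arange(kern_len + 1) / cfg.sample_rate_hz
    for etype, times in events.items():
        spec = kernels.get(etype)
        if spec is None or spec.amplitude_mm == 0 or len(np.atleast_1d(times)) == 0:
            continue
        k = spec.evaluate(tau)
        for ev in np.atleast_1d(times):
            if ev < 0 or ev > dur:
                raise ValueError(f"event time {ev} outside trial [0, {dur}]")
            i0 = int(round(ev * cfg.sample_rate_hz))
            i1 = min(i0 + len(k), len(t))
            pupil[i0:i1] += k[: i1 - i0]
    if noise and cfg.pupil_noise_sd_mm > 0:
        pupil = pupil + rng.normal(0, cfg.pupil_noise_sd_mm, len(t))
    if blinks is not None and len(blinks):
        pupil = pupil - _blink_occlusion(cfg, t, blinks)
    return pupil


def simulate_reports(
    switches: EventSeries,
    cfg: SimConfig,
    rng=None,
    duration_s: float | None = None,
    keymap: dict[str, str] | None = None,
) -> EventSeries:
    """Key presses lagging each non-missed switch by a truncated-normal delay.

    The key encodes the post-switch direction (``keymap`` can translate, e.g.
    inversion orientations to up/down arrows).
    """
    cfg.validate()
    rng = _rng_from(cfg.seed if rng is None else rng)
    dur = cfg.duration_s if duration_s is None else duration_s
    n = len(switches)
    if n == 0:
        return EventSeries.empty()
    delays = rng.normal(cfg.report_delay_mean_s, cfg.report_delay_sd_s, n)
    delays = np.clip(delays, 0.0, None)  # truncate at zero
    miss = rng.random(n) < cfg.report_miss_prob
    times = switches.times + delays
    keep = ~miss & (times <= dur)
    dirs = switches.directions[keep]
    if keymap is not None:
        dirs = np.array([keymap.get(d, d) for d in dirs], dtype=object)
    return EventSeries(
        times[keep], np.full(keep.sum(), "key_press", dtype=object), dirs
    )


def _true_kernel_curves(
    kernels: dict[str, KernelSpec], sample_rate_hz: float
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    grid = np.arange(
        int(round((PERI_WINDOW[1] - PERI_WINDOW[0]) * sample_rate_hz)) + 1
    ) / sample_rate_hz + PERI_WINDOW[0]
    return grid, {name: spec.evaluate(grid) for name, spec in kernels.items()}


def simulate_trial(
    cfg: SimConfig, condition: str, rng: np.random.Generator
) -> TrialData:
    """One trial: percepts -> gaze -> stimulus events -> pupil -> reports."""
    percepts, switches = simulate_percept_sequence(cfg, rng)
    inversions, _traj = simulate_stimulus_events(cfg, rng)
    gaze = simulate_okn_gaze(percepts, cfg, rng)
    kernels = cfg.kernels[condition]
    event_times = {
        "okn_switch": switches.times,
        "inversion": inversions.times,
        "blink": gaze.blinks.starts,
    }
    pupil = simulate_pupil(
        event_times, cfg, rng, blinks=gaze.blinks, kernels=kernels
    )
    if condition == "switch_relevant":
        reports = simulate_reports(switches, cfg, rng)
    else:
        reports = simulate_reports(inversions, cfg, rng)
    blink_onsets = EventSeries(
        gaze.blinks.starts,
        np.full(len(gaze.blinks), "blink_onset", dtype=object),
        None,
    )
    observed = EventSeries.concat([reports, inversions, blink_onsets])
    trace = RecordingTrace(
        gaze.t, gaze.xL, gaze.yL, gaze.xR, gaze.yR, pupil, gaze.valid
    )
    grid, true_k = _true_kernel_curves(kernels, cfg.sample_rate_hz)
    truth = GroundTruth(
        switch_times_s=switches.times,
        switch_directions=switches.directions,
        inversion_times_s=inversions.times,
        blink_intervals=gaze.blinks,
        saccade_intervals=gaze.saccades,
        report_times_s=reports.times,
        report_keys=reports.directions,
        kernel_grid=grid,
        true_kernels=true_k,
    )
    return TrialData(trace=trace, events=observed, truth=truth)


def simulate_session(cfg: SimConfig, observer: str = "sim") -> Session:
    """Full two-condition session (switch-relevant and inversion-relevant),
    ``cfg.n_trials`` trials each, reproducible from ``cfg.seed``."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.n_trials)
    conditions: dict[str, list[TrialData]] = {}
    i = 0
    for condition in ("switch_relevant", "inversion_relevant"):
        trials = []
        for _ in range(cfg.n_trials):
            trials.append(
                simulate_trial(cfg, condition, np.random.default_rng(children[i]))
            )
            i += 1
        conditions[condition] = trials
    return Session(config=cfg, conditions=conditions, observer=observer)


def simulate_study(
    cfg: SimConfig,
    n_observers: int,
    seed: int | None = None,
    dominance_spread: float = 0.3,
    amplitude_spread: float = 0.15,
) -> dict[str, Session]:
    """A cohort of observers with between-observer heterogeneity.

    Dominance means and kernel amplitudes vary lognormally across observers
    (individual switching tempo and pupil reactivity), which is what makes
    across-observer rate correlations informative.
    """
    base_seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    sessions: dict[str, Session] = {}
    for i in range(n_observers):
        dom = cfg.dominance_mean_s * float(
            np.exp(meta_rng.normal(0, dominance_spread))
        )
        amp = float(np.exp(meta_rng.normal(0, amplitude_spread)))
        kernels = {
            cond: {
                name: replace(spec, amplitude_mm=spec.amplitude_mm * amp)
                for name, spec in specs.items()
            }
            for cond, specs in cfg.kernels.items()
        }
        obs_cfg = replace(
            cfg,
            dominance_mean_s=dom,
            kernels=kernels,
            seed=int(meta_rng.integers(0, 2**31 - 1)),
        )
        obs_id = f"obs{i:02d}"
        sessions[obs_id] = simulate_session(obs_cfg, observer=obs_id)
    return sessions
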