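"""Gaze preprocessing: saccade/blink detection and the cleaned slow-phase
displacement trace.

Saccades are found per eye with the Engbert & Kliegl velocity-threshold
algorithm (5-point moving-window differentiation, median-based velocity SD,
elliptic threshold) and combined across eyes as the union of intervals.
Blinks are found from the pupil trace as periods opening with an unusually
rapid size decrease and closing with an unusually rapid increase (the eyelid
sweeping over and off the pupil).  The displacement trace accumulates
binocular gaze increments with saccade/blink/missing increments zeroed, so it
documents only slow-phase displacement.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import DisplacementTrace, IntervalSet, RecordingTrace


def _ek_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """5-point moving-window differentiation (Engbert & Kliegl)."""
    v = np.full(len(x), np.nan)
    if len(x) >= 5:
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    return v


def _median_sd(v: np.ndarray) -> float:
    """Median-based velocity SD estimator sqrt(<v^2> - <v>^2) with medians."""
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    sd2 = np.median(v**2) - np.median(v) ** 2
    return float(np.sqrt(max(sd2, 1e-12)))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) index pairs, half-open."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _monocular_saccades(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    lambda_mult: float,
    min_dur_s: float,
    min_thresh: float,
) -> list[tuple[float, float]]:
    dt = float(t[1] - t[0])
    out: list[tuple[float, float]] = []
    valid = np.isfinite(x) & np.isfinite(y)
    for i0, i1 in _runs(valid):
        if i1 - i0 < 5:
            continue
        vx = _ek_velocity(x[i0:i1], dt)
        vy = _ek_velocity(y[i0:i1], dt)
        sx = _median_sd(vx)
        sy = _median_sd(vy)
        if not np.isfinite(sx) or not np.isfinite(sy):
            continue
        eta_x = max(lambda_mult * sx, min_thresh)
        eta_y = max(lambda_mult * sy, min_thresh)
        with np.errstate(invalid="ignore"):
            crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
        crit = np.nan_to_num(crit).astype(bool)
        for s, e in _runs(crit):
            if (e - s) * dt >= min_dur_s:
                out.append((t[i0 + s], t[i0 + e - 1] + dt))
    return out


def detect_saccades(
    trace: RecordingTrace,
    lambda_mult: float = 6.0,
    min_dur_ms: float = 6.0,
    min_thresh_degps: float = 10.0,
) -> IntervalSet:
    """Engbert-Kliegl saccade detection per eye, combined across eyes (union).

    The per-axis elliptic threshold is ``lambda_mult`` times the median-based
    velocity SD, floored at ``min_thresh_degps`` so that nearly noise-free
    constant-velocity drift (where the median estimator degenerates to zero)
    stays sub-threshold while fast phases remain far above it.  Returns
    half-open intervals labeled ``saccade``; an all-invalid trace yields an
    empty set with a warning.
    """
    if not np.any(trace.valid):
        warnings.warn("trace has no valid samples; no saccades detected")
        return IntervalSet.empty()
    intervals: list[tuple[float, float]] = []
    for x, y in ((trace.xL, trace.yL), (trace.xR, trace.yR)):
        intervals.extend(
            _monocular_saccades(
                x, y, trace.t, lambda_mult, min_dur_ms / 1000.0, min_thresh_degps
            )
        )
    if not intervals:
        return IntervalSet.empty()
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    return IntervalSet(
        starts, ends, np.full(len(starts), "saccade", dtype=object)
    ).merged()


def detect_blinks(
    trace: RecordingTrace,
    rate_thresh: float = 10.0,
    merge_gap_ms: float = 100.0,
    smooth_ms: float = 10.0,
) -> IntervalSet:
    """Blinks = [rapid pupil decrease ... rapid pupil increase] periods.

    The pupil derivative is smoothed with a ``smooth_ms`` boxcar before
    thresholding at ±``rate_thresh`` mm/s.  Blinks closer than
    ``merge_gap_ms`` are merged; runs of invalid samples are labeled
    ``missing``.
    """
    t = trace.t
    dt = float(t[1] - t[0])
    pupil = np.asarray(trace.pupil, dtype=float)
    finite = np.isfinite(pupil)
    p = pupil.copy()
    if finite.any() and not finite.all():
        p[~finite] = np.interp(t[~finite], t[finite], pupil[finite])
    rate = np.gradient(p, dt)
    w = max(1, int(round(smooth_ms / 1000.0 / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        rate = np.convolve(rate, kernel, mode="same")

    starts: list[float] = []
    ends: list[float] = []
    n = len(t)
    i = 0
    while i < n:
        if rate[i] < -rate_thresh:
            onset = i
            # skip through the downward run, then look for the recovery
            j = onset
            while j < n and not rate[j] > rate_thresh:
                j += 1
            if j >= n:
                break
            # extend through the whole upward (recovery) run
            while j + 1 < n and rate[j + 1] > rate_thresh:
                j += 1
            starts.append(t[onset])
            ends.append(t[j] + dt)
            i = j + 1
        else:
            i += 1

    blink_set = (
        IntervalSet(
            np.array(starts),
            np.array(ends),
            np.full(len(starts), "blink", dtype=object),
        ).merged(gap=merge_gap_ms / 1000.0)
        if starts
        else IntervalSet.empty()
    )
    # invalid samples not already inside a blink -> missing
    invalid = ~np.asarray(trace.valid, dtype=bool)
    invalid &= ~blink_set.mask(t)
    missing: list[tuple[float, float]] = [
        (t[s], t[e - 1] + dt) for s, e in _runs(invalid)
    ]
    if missing:
        ms = np.array([s for s, _ in missing])
        me = np.array([e for _, e in missing])
        miss_set = IntervalSet(ms, me, np.full(len(ms), "missing", dtype=object))
        return blink_set.union(miss_set)
    return blink_set


def build_clean_displacement(
    trace: RecordingTrace, artifacts: IntervalSet
) -> DisplacementTrace:
    """Cumulative binocular gaze displacement with artifact increments zeroed.

    Per-sample increments of the binocular-average position are set to zero
    inside any saccade/blink/missing interval (and wherever the position is
    undefined), then accumulated from zero.
    """
    x, y = trace.binocular_gaze()
    t = trace.t
    bad = artifacts.mask(t)
    dx = np.diff(x, prepend=x[0] if len(x) else 0.0)
    dy = np.diff(y, prepend=y[0] if len(y) else 0.0)
    dx[0] = 0.0
    dy[0] = 0.0
    undef = ~np.isfinite(dx) | ~np.isfinite(dy)
    # an increment touches samples i-1 and i; zero it if either is flagged
    touch = bad.copy()
    touch[1:] |= bad[:-1]
    kill = touch | undef
    dx[kill] = 0.0
    dy[kill] = 0.0
    return DisplacementTrace(t, np.cumsum(dx), np.cumsum(dy))


def fill_blink_buffers(
    disp: DisplacementTrace,
    blinks: IntervalSet,
    pre_ms: float = 250.0,
    post_ms: float = 400.0,
    flank_ms: float = 100.0,
) -> DisplacementTrace:
    """Replace displacement increments around blinks with the local mean rate.

    Increments from ``pre_ms`` before each blink to ``post_ms`` after it are
    replaced (per component) by the mean increment over the ``flank_ms``
    windows immediately outside that buffer, and the cumulative trace is
    rebuilt.  This keeps long blink gaps from contaminating the displacement
    angle near blinks.
    """
    t = disp.t
    dt = float(t[1] - t[0])
    dx = np.diff(disp.x, prepend=disp.x[0])
    dy = np.diff(disp.y, prepend=disp.y[0])
    dx[0] = 0.0
    dy[0] = 0.0
    pre, post, flank = pre_ms / 1000.0, post_ms / 1000.0, flank_ms / 1000.0
    for s, e, label in blinks:
        if label not in ("blink", "missing"):
            continue
        buf_lo, buf_hi = s - pre, e + post
        in_buf = (t >= buf_lo) & (t < buf_hi)
        if not in_buf.any():
            continue
        left = (t >= buf_lo - flank) & (t < buf_lo)
        right = (t >= buf_hi) & (t < buf_hi + flank)
        flank_mask = left | right
        if not flank_mask.any():
            mean_dx = mean_dy = 0.0
        else:
            mean_dx = float(np.mean(dx[flank_mask]))
            mean_dy = float(np.mean(dy[flank_mask]))
        dx[in_buf] = mean_dx
        dy[in_buf] = mean_dy
    _ = dt
    return DisplacementTrace(t, np.cumsum(dx), np.cumsum(dy))


def preprocess_gaze(
    trace: RecordingTrace,
    lambda_mult: float = 6.0,
    min_dur_ms: float = 6.0,
    rate_thresh: float = 10.0,
    merge_gap_ms: float = 100.0,
) -> tuple[DisplacementTrace, IntervalSet, IntervalSet]:
    """Full gaze-cleaning stage: detect artifacts, zero their increments,
    bridge blink buffers.  Returns (displacement, saccades, blinks+missing)."""
    saccades = detect_saccades(trace, lambda_mult, min_dur_ms)
    blinks = detect_blinks(trace, rate_thresh, merge_gap_ms)
    artifacts = saccades.union(blinks)
    disp = build_clean_displacement(trace, artifacts)
    disp = fill_blink_buffers(disp, blinks)
    return disp, saccades, blinks
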