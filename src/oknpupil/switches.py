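"""OKN-based perceptual switch detection.

The cleaned slow-phase displacement trace is scanned with a sliding window
(1500 ms, stepped by 38 ms).  Within each window ordinary least-squares lines
are fit to horizontal and vertical displacement versus time; the arctangent
of the two slopes is the gaze displacement angle.  Windows whose angle cosine
exceeds +0.7 are tentatively labeled rightward perceived motion, below -0.7
leftward, otherwise unassigned.  A switch is marked midway between each pair
of consecutive opposite assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import DisplacementTrace, EventSeries


@dataclass
class AngleWindowSeries:
    """Per-window displacement angle, its cosine, and the percept label."""

    center_s: np.ndarray
    angle_rad: np.ndarray
    cos_val: np.ndarray
    label: np.ndarray  # "left" | "right" | "unassigned"

    def __len__(self) -> int:
        return len(self.center_s)


def _sliding_slopes(
    t: np.ndarray, v: np.ndarray, starts: np.ndarray, win: int
) -> np.ndarray:
    """OLS slope of v on t for each window [s, s+win), vectorized via cumsums.

    slope = (n*Sxy - Sx*Sy) / (n*Sxx - Sx^2) with sums over the window.
    """
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cv = np.concatenate([[0.0], np.cumsum(v)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    ctv = np.concatenate([[0.0], np.cumsum(t * v)])
    e = starts + win
    n = float(win)
    sx = ct[e] - ct[starts]
    sy = cv[e] - cv[starts]
    sxx = ctt[e] - ctt[starts]
    sxy = ctv[e] - ctv[starts]
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
    return slope


def window_angles(
    disp: DisplacementTrace, win_ms: float = 1500.0, step_ms: float = 38.0
) -> AngleWindowSeries:
    """Gaze displacement angle per sliding window, full-circle (atan2).

    Only windows lying fully inside the trial are evaluated.  Cumulative-sum
    arithmetic makes this O(n) over the trace; to keep the closed-form
    least-squares numerically exact, time is re-centered per trace before the
    fit (slopes are translation invariant).
    """
    t = disp.t
    dt = float(t[1] - t[0])
    win = int(round(win_ms / 1000.0 / dt))
    step = max(1, int(round(step_ms / 1000.0 / dt)))
    if win < 2 or len(t) < win:
        raise ValueError("trace shorter than one window")
    starts = np.arange(0, len(t) - win + 1, step)
    tc = t - t[0]  # guard cumsum precision on long trials
    sx = _sliding_slopes(tc, disp.x, starts, win)
    sy = _sliding_slopes(tc, disp.y, starts, win)
    angle = np.arctan2(sy, sx)
    cos_val = np.cos(angle)
    bad = ~np.isfinite(sx) | ~np.isfinite(sy)
    angle[bad] = np.nan
    cos_val[bad] = np.nan
    centers = t[starts] + (win - 1) * dt / 2.0
    label = np.full(len(starts), "unassigned", dtype=object)
    return AngleWindowSeries(centers, angle, cos_val, label)


def classify_windows(
    series: AngleWindowSeries, cos_thresh: float = 0.7
) -> AngleWindowSeries:
    """Label windows by the cosine of the displacement angle.

    cos < -thresh -> leftward perceived front-surface motion; cos > +thresh
    -> rightward; intermediate (or undefined) -> unassigned.  Inequalities
    are strict, so a cosine exactly at the threshold stays unassigned.
    """
    label = np.full(len(series), "unassigned", dtype=object)
    with np.errstate(invalid="ignore"):
        label[series.cos_val < -cos_thresh] = "left"
        label[series.cos_val > cos_thresh] = "right"
    return AngleWindowSeries(series.center_s, series.angle_rad, series.cos_val, label)


def extract_switches(
    series: AngleWindowSeries, min_run_s: float = 0.0
) -> EventSeries:
    """Mark a switch midway between consecutive opposite assigned windows.

    Unassigned windows between the pair are skipped; repeats of the same
    label emit nothing, so output directions strictly alternate.  An optional
    debounce (``min_run_s`` > 0) ignores assigned runs shorter than that
    duration; it is off by default.
    """
    assigned = series.label != "unassigned"
    idx = np.flatnonzero(assigned)
    if len(idx) < 2:
        return EventSeries.empty()
    centers = series.center_s[idx]
    labels = series.label[idx]
    if min_run_s > 0:
        keep = _debounce(centers, labels, min_run_s)
        centers, labels = centers[keep], labels[keep]
        if len(centers) < 2:
            return EventSeries.empty()
    times: list[float] = []
    dirs: list[str] = []
    prev_label = labels[0]
    prev_center = centers[0]
    for c, lab in zip(centers[1:], labels[1:]):
        if lab != prev_label:
            times.append((prev_center + c) / 2.0)
            dirs.append(lab)
        prev_label, prev_center = lab, c
    return EventSeries(
        np.array(times),
        np.full(len(times), "okn_switch", dtype=object),
        np.array(dirs, dtype=object),
    )


def _debounce(centers: np.ndarray, labels: np.ndarray, min_run_s: float) -> np.ndarray:
    """Keep only windows belonging to same-label runs spanning >= min_run_s."""
    keep = np.zeros(len(labels), dtype=bool)
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        if centers[j] - centers[i] >= min_run_s:
            keep[i : j + 1] = True
        i = j + 1
    return keep


def detect_okn_switches(
    disp: DisplacementTrace,
    win_ms: float = 1500.0,
    step_ms: float = 38.0,
    cos_thresh: float = 0.7,
    min_run_s: float = 0.0,
) -> EventSeries:
    """Convenience: window -> classify -> extract in one call."""
    series = classify_windows(window_angles(disp, win_ms, step_ms), cos_thresh)
    return extract_switches(series, min_run_s)
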