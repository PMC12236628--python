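"""Pupil preprocessing: artifact interpolation and slow-drift removal.

Pupil size is linearly interpolated across blink and missing-data intervals
(slightly padded, to avoid eyelid-edge artifacts), then detrended by
subtracting a 15-s sliding boxcar average, which removes gradual changes in
pupil size but not faster fluctuations.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import IntervalSet, PupilTrace, RecordingTrace


def interpolate_artifacts(
    trace: RecordingTrace | PupilTrace,
    artifacts: IntervalSet,
    pad_ms: float = 100.0,
) -> PupilTrace:
    """Linearly interpolate pupil size across (padded) artifact intervals.

    Samples inside each interval, extended by ``pad_ms`` on both sides, are
    replaced by the straight line joining the flanking valid samples; gaps at
    the trial edges are filled with the nearest valid value.
    """
    t = trace.t
    pupil = np.asarray(trace.pupil, dtype=float).copy()
    bad = artifacts.mask(t, pad=pad_ms / 1000.0)
    bad |= ~np.isfinite(pupil)
    if bad.all():
        raise ValueError("entire trial is artifactual; cannot interpolate")
    good = ~bad
    pupil[bad] = np.interp(t[bad], t[good], pupil[good])
    return PupilTrace(t, pupil, stage="interpolated")


def _truncated_boxcar_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average, window truncated symmetrically at the edges.

    At sample i the half-width is min(half, i, n-1-i), so the window stays
    centered and the output length equals the input length.
    """
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    h = np.minimum(half, np.minimum(i, n - 1 - i))
    lo = i - h
    hi = i + h + 1
    return (c[hi] - c[lo]) / (hi - lo)


def remove_slow_drift(trace: PupilTrace, boxcar_s: float = 15.0) -> PupilTrace:
    """Subtract the sliding-boxcar-smoothed pupil signal (high-pass).

    The boxcar is centered and truncated symmetrically at trial edges.
    Trials shorter than the boxcar get their mean subtracted, with a warning.
    """
    t = trace.t
    pupil = np.asarray(trace.pupil, dtype=float)
    dt = float(t[1] - t[0])
    if t[-1] - t[0] < boxcar_s:
        warnings.warn("trial shorter than boxcar window; subtracting trial mean")
        return PupilTrace(t, pupil - pupil.mean(), stage="detrended")
    half = int(round(boxcar_s / dt / 2.0))
    smooth = _truncated_boxcar_mean(pupil, half)
    return PupilTrace(t, pupil - smooth, stage="detrended")


def preprocess_pupil(
    trace: RecordingTrace,
    artifacts: IntervalSet,
    pad_ms: float = 100.0,
    boxcar_s: float = 15.0,
) -> PupilTrace:
    """Interpolate artifacts then remove slow drift."""
    return remove_slow_drift(interpolate_artifacts(trace, artifacts, pad_ms), boxcar_s)
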