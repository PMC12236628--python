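"""Fourier-basis GLM deconvolution of event-related pupil responses.

The detrended pupil signal is modeled as a superposition of unknown
event-locked impulse responses, one per event type (triangle inversions,
OKN-based switches, blinks), each expressed as a weighted sum of Fourier
basis functions (a constant plus sine/cosine pairs) over a peri-event window
running from 2 s before to 6 s after the event.  Ordinary least squares on
the concatenated trials recovers the weights; multiplying back through the
basis yields the response curves.  Overlapping responses are handled
naturally by the linearity of the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ResponseCurve

DEFAULT_WINDOW = (-2.0, 6.0)
ALLOWED_REGRESSORS = ("inversion", "okn_switch", "manual_switch", "key_press", "blink")


@dataclass
class BasisSet:
    """Fourier basis evaluated on the peri-event grid.

    ``columns`` has shape (len(grid), 2*order+1): a constant column followed
    by sine/cosine pairs with periods window_length / k, k = 1..order.
    """

    window: tuple[float, float]
    order: int
    grid: np.ndarray
    columns: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def make_fourier_basis(
    order: int, window: tuple[float, float] = DEFAULT_WINDOW, dt: float = 0.02
) -> BasisSet:
    """Constant + ``order`` sine/cosine pairs on a uniform peri-event grid."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive length")
    n = int(round((w1 - w0) / dt)) + 1
    grid = w0 + np.arange(n) * dt
    length = w1 - w0
    cols = [np.ones(n)]
    phase = 2.0 * np.pi * (grid - w0) / length
    for k in range(1, order + 1):
        cols.append(np.sin(k * phase))
        cols.append(np.cos(k * phase))
    return BasisSet(window=(w0, w1), order=order, grid=grid, columns=np.column_stack(cols))


@dataclass
class DesignMatrix:
    """Concatenated-trial design: per-event-type basis blocks + per-trial
    intercepts.  ``col_slices`` maps each event type to its column block."""

    X: np.ndarray
    event_types: tuple[str, ...]
    col_slices: dict[str, slice]
    n_trials: int
    basis: BasisSet

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_design_matrix(
    events_by_trial: list[dict[str, np.ndarray]],
    basis: BasisSet,
    t_by_trial: list[np.ndarray],
    event_types: tuple[str, ...] | None = None,
) -> DesignMatrix:
    """Place a time-shifted copy of the basis at every event.

    For each event, each basis column is added into that event type's column
    block, shifted so basis time 0 aligns with the event; contributions
    crossing trial boundaries are truncated.  One intercept column per trial
    is appended.  The signal grids must share the basis sample step.
    """
    if event_types is None:
        seen: list[str] = []
        for ev in events_by_trial:
            for k in ev:
                if k not in seen:
                    seen.append(k)
        event_types = tuple(seen)
    for et in event_types:
        if et not in ALLOWED_REGRESSORS:
            raise ValueError(f"unknown event type {et!r}")
    nb = basis.n_columns
    dt = float(basis.grid[1] - basis.grid[0])
    n_trials = len(t_by_trial)
    n_rows = sum(len(t) for t in t_by_trial)
    X = np.zeros((n_rows, len(event_types) * nb + n_trials))
    col_slices = {
        et: slice(i * nb, (i + 1) * nb) for i, et in enumerate(event_types)
    }
    k0 = int(round(basis.window[0] / dt))  # sample offset of the window start
    nbas = len(basis.grid)
    row0 = 0
    for tr, (t, events) in enumerate(zip(t_by_trial, events_by_trial)):
        n = len(t)
        sig_dt = float(t[1] - t[0])
        if not np.isclose(sig_dt, dt, rtol=1e-6):
            raise ValueError("signal sample step must match the basis grid step")
        for et in event_types:
            times = np.atleast_1d(np.asarray(events.get(et, []), dtype=float))
            if len(times) and (times.min() < t[0] or times.max() > t[-1]):
                raise ValueError(f"{et} event outside trial {tr}")
            block = X[row0 : row0 + n, col_slices[et]]
            for ev in times:
                i_ev = int(round((ev - t[0]) / dt))
                lo = i_ev + k0
                hi = lo + nbas
                b_lo = max(0, -lo)
                b_hi = nbas - max(0, hi - n)
                if b_lo >= b_hi:
                    continue
                block[lo + b_lo : lo + b_hi, :] += basis.columns[b_lo:b_hi, :]
        X[row0 : row0 + n, len(event_types) * nb + tr] = 1.0
        row0 += n
    return DesignMatrix(X, event_types, col_slices, n_trials, basis)


@dataclass
class DeconvolutionFit:
    coefficients: dict[str, np.ndarray]
    intercepts: np.ndarray
    design: DesignMatrix
    rank: int


def fit_deconvolution(signal: np.ndarray, design: DesignMatrix) -> DeconvolutionFit:
    """Ordinary least squares of the pupil vector on the design matrix.

    Rank deficiency falls back to the minimal-norm least-squares solution
    with a warning; residuals are orthogonal to the design columns either
    way.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != design.X.shape[0]:
        raise ValueError("signal length does not match design rows")
    beta, _, rank, _ = np.linalg.lstsq(design.X, signal, rcond=None)
    if rank < design.n_columns:
        warnings.warn(
            f"design matrix rank deficient ({rank}/{design.n_columns}); "
            "returning minimal-norm solution"
        )
    coeffs = {et: beta[sl] for et, sl in design.col_slices.items()}
    intercepts = beta[len(design.event_types) * design.basis.n_columns :]
    return DeconvolutionFit(coeffs, intercepts, design, int(rank))


def reconstruct_responses(
    fit_or_coeffs: DeconvolutionFit | dict[str, np.ndarray],
    basis: BasisSet | None = None,
    observer: str = "",
    condition: str = "",
) -> dict[str, ResponseCurve]:
    """Response curve per event type: basis @ coefficients on the peri grid."""
    if isinstance(fit_or_coeffs, DeconvolutionFit):
        coeffs = fit_or_coeffs.coefficients
        basis = fit_or_coeffs.design.basis
    else:
        coeffs = fit_or_coeffs
        if basis is None:
            raise ValueError("basis required when passing raw coefficients")
    out: dict[str, ResponseCurve] = {}
    for et, c in coeffs.items():
        if len(c) != basis.n_columns:
            raise ValueError(f"coefficient length mismatch for {et}")
        out[et] = ResponseCurve(
            t_peri=basis.grid,
            value=basis.columns @ c,
            observer=observer,
            condition=condition,
            event_type=et,
        )
    return out


def downsample(t: np.ndarray, x: np.ndarray, fs_target: float) -> tuple[np.ndarray, np.ndarray]:
    """Block-average downsampling to ``fs_target`` (anti-aliasing boxcar)."""
    fs_in = 1.0 / float(t[1] - t[0])
    factor = int(round(fs_in / fs_target))
    if factor <= 1:
        return t, x
    n = (len(t) // factor) * factor
    t_ds = t[:n].reshape(-1, factor).mean(axis=1)
    x_ds = x[:n].reshape(-1, factor).mean(axis=1)
    return t_ds, x_ds


def deconvolve_trials(
    trials: list[tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]],
    order: int = 6,
    window: tuple[float, float] = DEFAULT_WINDOW,
    fs_fit: float = 50.0,
    observer: str = "",
    condition: str = "",
    event_types: tuple[str, ...] | None = None,
) -> dict[str, ResponseCurve]:
    """End-to-end deconvolution of one observer x condition.

    ``trials`` is a list of (t, detrended_pupil, events) with ``events``
    mapping event type to times.  The signal is block-averaged down to
    ``fs_fit`` before fitting (the basis uses the same step).
    """
    t_ds_list, x_ds_list = [], []
    for t, x, _ in trials:
        t_ds, x_ds = downsample(np.asarray(t, float), np.asarray(x, float), fs_fit)
        t_ds_list.append(t_ds)
        x_ds_list.append(x_ds)
    dt = float(t_ds_list[0][1] - t_ds_list[0][0])
    basis = make_fourier_basis(order, window, dt)
    events_by_trial = []
    for (t, _, events), t_ds in zip(trials, t_ds_list):
        clipped = {}
        for et, times in events.items():
            times = np.atleast_1d(np.asarray(times, dtype=float))
            clipped[et] = times[(times >= t_ds[0]) & (times <= t_ds[-1])]
        events_by_trial.append(clipped)
    design = build_design_matrix(events_by_trial, basis, t_ds_list, event_types)
    fit = fit_deconvolution(np.concatenate(x_ds_list), design)
    return reconstruct_responses(fit, observer=observer, condition=condition)
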