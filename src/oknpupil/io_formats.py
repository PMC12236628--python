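"""Tidy delimited file formats for samples, events, intervals, and curves.

Sample files: ``time_s,xL_deg,yL_deg,xR_deg,yR_deg,pupil_mm,valid`` with one
row per sample on a uniform time base starting at 0.  Event files:
``time_s,type,direction`` with type in {key_press, okn_switch,
manual_switch, inversion, blink_onset}.  Interval files:
``start_s,end_s,label``.  All times in seconds, intervals half-open.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EVENT_TYPES, EventSeries, IntervalSet, RecordingTrace

SAMPLE_COLUMNS = ["time_s", "xL_deg", "yL_deg", "xR_deg", "yR_deg", "pupil_mm", "valid"]
EVENT_COLUMNS = ["time_s", "type", "direction"]
FLOAT_FORMAT = "%.6f"


def write_samples(trace: RecordingTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.t,
            "xL_deg": trace.xL,
            "yL_deg": trace.yL,
            "xR_deg": trace.xR,
            "yR_deg": trace.yR,
            "pupil_mm": trace.pupil,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_samples(path) -> RecordingTrace:
    """Parse and validate a sample CSV (uniform, strictly increasing time)."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = {}
    for col in SAMPLE_COLUMNS[:-1]:
        vals = pd.to_numeric(df[col], errors="coerce")
        fresh_nan = vals.isna() & df[col].notna()
        if fresh_nan.any():
            lines = (df.index[fresh_nan] + 2).tolist()[:5]  # +2: header + 0-base
            raise ValueError(f"{path}: non-numeric cells in {col!r} at lines {lines}")
        numeric[col] = vals.to_numpy(float)
    t = numeric["time_s"]
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.flatnonzero(dt <= 0)[0]) + 3
            raise ValueError(f"{path}: timestamps not strictly increasing at line {line}")
        if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
            raise ValueError(f"{path}: non-uniform time base")
    valid = df["valid"].astype(bool).to_numpy()
    return RecordingTrace(
        t,
        numeric["xL_deg"],
        numeric["yL_deg"],
        numeric["xR_deg"],
        numeric["yR_deg"],
        numeric["pupil_mm"],
        valid,
    )


def write_events(events: EventSeries, path) -> None:
    events.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_events(path) -> EventSeries:
    """Parse an events CSV into a typed, time-sorted series."""
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        return EventSeries.empty()
    missing = [c for c in ("time_s", "type") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        return EventSeries.empty()
    unknown = set(df["type"]) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"{path}: unknown event types {sorted(unknown)}")
    dupes = df.duplicated(subset=["time_s", "type"])
    if dupes.any():
        warnings.warn(
            f"{path}: {int(dupes.sum())} duplicate (time, type) rows preserved"
        )
    return EventSeries.from_frame(df).sorted()


def write_intervals(intervals: IntervalSet, path) -> None:
    intervals.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_intervals(path) -> IntervalSet:
    df = pd.read_csv(path)
    if df.empty:
        return IntervalSet.empty()
    return IntervalSet.from_frame(df)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration document."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_session(session, out_dir, kernel_fs_hz: float = 50.0) -> None:
    """Write a simulated session: per-trial sample/event CSVs plus a
    ground-truth JSON sidecar (kernels stored at ``kernel_fs_hz``)."""
    out_dir = Path(out_dir)
    truth_doc: dict = {"observer": session.observer, "conditions": {}}
    for condition, trials in session.conditions.items():
        cdir = out_dir / session.observer / condition
        cdir.mkdir(parents=True, exist_ok=True)
        cond_truth = []
        for i, trial in enumerate(trials):
            write_samples(trial.trace, cdir / f"trial{i:02d}_samples.csv")
            write_events(trial.events, cdir / f"trial{i:02d}_events.csv")
            tr = trial.truth
            step = max(1, int(round(session.config.sample_rate_hz / kernel_fs_hz)))
            cond_truth.append(
                {
                    "switch_times_s": tr.switch_times_s.tolist(),
                    "switch_directions": tr.switch_directions.tolist(),
                    "inversion_times_s": tr.inversion_times_s.tolist(),
                    "blink_intervals": tr.blink_intervals.to_frame().to_dict("list"),
                    "saccade_intervals": tr.saccade_intervals.to_frame().to_dict("list"),
                    "report_times_s": tr.report_times_s.tolist(),
                    "report_keys": tr.report_keys.tolist(),
                    "kernel_grid": tr.kernel_grid[::step].tolist(),
                    "true_kernels": {
                        k: v[::step].tolist() for k, v in tr.true_kernels.items()
                    },
                }
            )
        truth_doc["conditions"][condition] = cond_truth
    with open(out_dir / session.observer / "ground_truth.json", "w") as fh:
        json.dump(truth_doc, fh)


def read_session_trials(session_dir, observer: str, condition: str):
    """Load (trace, events) pairs for one observer x condition directory."""
    cdir = Path(session_dir) / observer / condition
    trials = []
    for sample_path in sorted(cdir.glob("trial*_samples.csv")):
        event_path = Path(str(sample_path).replace("_samples.csv", "_events.csv"))
        trials.append((read_samples(sample_path), read_events(event_path)))
    if not trials:
        raise FileNotFoundError(f"no trials under {cdir}")
    return trials


def convert_eyelink_asc(path):  # pragma: no cover - documented stub
    """Placeholder for native EyeLink ASC ingestion (not part of the core).

    The intended mapping: SAMPLE lines -> ``time_s`` (ms/1000, re-zeroed per
    trial), left/right gaze x/y converted from pixels to degrees using the
    display geometry -> ``xL_deg..yR_deg``, pupil area/diameter -> ``pupil_mm``
    via the tracker's calibration, blink/missing markers -> ``valid``;
    MSG lines carrying trial/stimulus markers -> the events CSV.
    """
    raise NotImplementedError(
        "EyeLink ASC conversion is out of scope; export tidy CSVs instead"
    )
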