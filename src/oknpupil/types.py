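"""Shared containers for gaze/pupil time series, labeled intervals, and events.

Conventions used throughout the package:

* times are in seconds from trial start, on a uniform grid;
* gaze positions are in degrees of visual angle, x positive rightward,
  y positive upward; pupil diameter is in millimetres;
* intervals are half-open ``[start_s, end_s)``;
* sample indexing is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

INTERVAL_LABELS = ("saccade", "blink", "missing")
EVENT_TYPES = ("key_press", "okn_switch", "manual_switch", "inversion", "blink_onset")


@dataclass
class RecordingTrace:
    """Synchronized binocular gaze + pupil recording for one trial.

    ``valid`` flags samples that carry usable data; invalid samples are kept
    in place (never dropped) so that the time base stays uniform.
    """

    t: np.ndarray
    xL: np.ndarray
    yL: np.ndarray
    xR: np.ndarray
    yR: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.t, self.xL, self.yL, self.xR, self.yR, self.pupil, self.valid]
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise ValueError("all trace arrays must have equal length")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time base must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time base must be uniform")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def sample_rate(self) -> float:
        if len(self.t) < 2:
            raise ValueError("need >= 2 samples to infer sample rate")
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.sample_rate

    def binocular_gaze(self) -> tuple[np.ndarray, np.ndarray]:
        """Average of the two eyes; falls back to the valid eye when one is NaN."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            x = np.nanmean(np.vstack([self.xL, self.xR]), axis=0)
            y = np.nanmean(np.vstack([self.yL, self.yR]), axis=0)
        return x, y


@dataclass
class IntervalSet:
    """Labeled half-open time intervals (saccade / blink / missing) on a trial."""

    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.starts) == len(self.ends) == len(self.labels)):
            raise ValueError("interval arrays must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must satisfy start < end")
        bad = set(self.labels) - set(INTERVAL_LABELS)
        if bad:
            raise ValueError(f"unknown interval labels: {sorted(bad)}")

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=object))

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts, self.ends, self.labels))

    def with_label(self, label: str) -> "IntervalSet":
        m = self.labels == label
        return IntervalSet(self.starts[m], self.ends[m], self.labels[m])

    def merged(self, gap: float = 0.0) -> "IntervalSet":
        """Merge overlapping (or closer-than-``gap``) intervals per label."""
        starts, ends, labels = [], [], []
        for label in INTERVAL_LABELS:
            sub = self.with_label(label)
            if len(sub) == 0:
                continue
            order = np.argsort(sub.starts, kind="stable")
            s, e = sub.starts[order], sub.ends[order]
            cs, ce = s[0], e[0]
            for i in range(1, len(s)):
                if s[i] <= ce + gap:
                    ce = max(ce, e[i])
                else:
                    starts.append(cs)
                    ends.append(ce)
                    labels.append(label)
                    cs, ce = s[i], e[i]
            starts.append(cs)
            ends.append(ce)
            labels.append(label)
        out = IntervalSet(np.array(starts), np.array(ends), np.array(labels, dtype=object))
        order = np.argsort(out.starts, kind="stable")
        return IntervalSet(out.starts[order], out.ends[order], out.labels[order])

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(
            np.concatenate([self.starts, other.starts]),
            np.concatenate([self.ends, other.ends]),
            np.concatenate([self.labels, other.labels]),
        ).merged()

    def mask(self, t: np.ndarray, pad: float = 0.0) -> np.ndarray:
        """Boolean mask of samples falling inside any interval (padded by ``pad``)."""
        t = np.asarray(t)
        m = np.zeros(len(t), dtype=bool)
        for s, e, _ in self:
            m |= (t >= s - pad) & (t < e + pad)
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.starts, "end_s": self.ends, "label": self.labels}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        return cls(
            df["start_s"].to_numpy(float),
            df["end_s"].to_numpy(float),
            df["label"].to_numpy(object),
        )


@dataclass
class EventSeries:
    """Timestamped labeled events with an optional direction per event.

    ``directions`` entries are ``"left"``, ``"right"``, ``"up"``, ``"down"``
    or ``""`` (no direction).
    """

    times: np.ndarray
    types: np.ndarray
    directions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.types = np.asarray(self.types, dtype=object)
        if self.directions is None:
            self.directions = np.full(len(self.times), "", dtype=object)
        self.directions = np.asarray(self.directions, dtype=object)
        if not (len(self.times) == len(self.types) == len(self.directions)):
            raise ValueError("event arrays must have equal length")

    @classmethod
    def empty(cls) -> "EventSeries":
        return cls(np.empty(0), np.empty(0, dtype=object), np.empty(0, dtype=object))

    def __len__(self) -> int:
        return len(self.times)

    def of_type(self, event_type: str) -> "EventSeries":
        m = self.types == event_type
        return EventSeries(self.times[m], self.types[m], self.directions[m])

    def sorted(self) -> "EventSeries":
        order = np.argsort(self.times, kind="stable")
        return EventSeries(self.times[order], self.types[order], self.directions[order])

    def shifted(self, dt: float) -> "EventSeries":
        return replace(self, times=self.times + dt)

    @classmethod
    def concat(cls, series: list["EventSeries"]) -> "EventSeries":
        if not series:
            return cls.empty()
        return cls(
            np.concatenate([s.times for s in series]),
            np.concatenate([s.types for s in series]),
            np.concatenate([s.directions for s in series]),
        ).sorted()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "type": self.types, "direction": self.directions}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSeries":
        direction = (
            df["direction"].fillna("").astype(str).to_numpy(object)
            if "direction" in df
            else None
        )
        return cls(df["time_s"].to_numpy(float), df["type"].to_numpy(object), direction)


@dataclass
class DisplacementTrace:
    """Cumulative cleaned slow-phase gaze displacement (degrees) from trial start."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("displacement arrays must have equal length")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class PupilTrace:
    """Pupil diameter series with a processing-stage tag."""

    t: np.ndarray
    pupil: np.ndarray
    stage: str = "raw"  # raw | interpolated | detrended

    def __post_init__(self) -> None:
        if len(self.t) != len(self.pupil):
            raise ValueError("pupil arrays must have equal length")
        if self.stage not in ("raw", "interpolated", "detrended"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class ResponseCurve:
    """Event-related pupil (or pupil-derivative) curve on the peri-event grid."""

    t_peri: np.ndarray
    value: np.ndarray
    observer: str = ""
    condition: str = ""
    event_type: str = ""
    units: str = "mm"

    def __post_init__(self) -> None:
        if len(self.t_peri) != len(self.value):
            raise ValueError("curve arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observer": self.observer,
                "condition": self.condition,
                "event_type": self.event_type,
                "t_peri": self.t_peri,
                "value": self.value,
            }
        )


@dataclass
class Cluster:
    """A maximal run of consecutive same-sign significant time points."""

    start_idx: int
    end_idx: int  # inclusive
    sign: int  # +1 or -1
    mass: float  # sum of member t-scores
    p_mc: float = np.nan

    @property
    def n_points(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class ClusterTestResult:
    """Observed clusters with Monte Carlo p-values plus the permutation null."""

    clusters: list[Cluster]
    null_masses: np.ndarray
    t_series: np.ndarray
    p_series: np.ndarray
    grid: np.ndarray
    alpha_cluster: float
    alpha_point: float
    flagged_zero_variance: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_mc < self.alpha_cluster]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "start_s": float(self.grid[c.start_idx]),
                    "end_s": float(self.grid[c.end_idx]),
                    "sign": c.sign,
                    "mass": c.mass,
                    "p_mc": c.p_mc,
                    "significant": bool(c.p_mc < self.alpha_cluster),
                }
            )
        return pd.DataFrame(
            rows, columns=["start_s", "end_s", "sign", "mass", "p_mc", "significant"]
        )
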