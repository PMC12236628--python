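"""OKN validation analyses and observer-exclusion rules.

Manual switches are read off the key-press record (a press counts as a
switch only when its direction differs from the previous press), observers
failing task-compliance criteria are excluded, OKN-based and manual switch
rates are correlated across observers, and peri-event histograms check the
temporal alignment between OKN-based switches and key presses (or triangle
inversions, as a negative control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import EventSeries

_DIRECTIONAL_KEYS = {"left", "right", "up", "down"}


@dataclass
class ObserverSummary:
    """Per-observer, per-condition compliance and rate metrics."""

    observer: str
    condition: str
    manual_rate_per_min: float = np.nan
    okn_rate_per_min: float = np.nan
    alternation_fraction: float = np.nan
    n_presses: int = 0
    n_inversions: int = 0
    task_order: str = ""

    @property
    def press_to_inversion_ratio(self) -> float:
        if self.n_inversions == 0:
            return np.inf if self.n_presses else np.nan
        return self.n_presses / self.n_inversions


def extract_manual_switches(presses: EventSeries) -> EventSeries:
    """Presses whose direction differs from the previous press are switches.

    The first press is never a switch; repeats of the previous direction are
    ignored, so output directions strictly alternate.
    """
    presses = presses.sorted()
    for d in presses.directions:
        if d not in _DIRECTIONAL_KEYS:
            raise ValueError(
                f"non-directional key {d!r}; manual switches need directional presses"
            )
    times, dirs = [], []
    prev = None
    for t, d in zip(presses.times, presses.directions):
        if prev is not None and d != prev:
            times.append(t)
            dirs.append(d)
        prev = d
    return EventSeries(
        np.array(times),
        np.full(len(times), "manual_switch", dtype=object),
        np.array(dirs, dtype=object),
    )


def alternation_fraction(presses: EventSeries) -> float:
    """Fraction of presses (after the first) that change direction."""
    if len(presses) < 2:
        return np.nan
    presses = presses.sorted()
    changes = sum(
        1
        for a, b in zip(presses.directions[:-1], presses.directions[1:])
        if a != b
    )
    return changes / (len(presses) - 1)


def qc_exclude_observers(
    summaries: list[ObserverSummary],
    min_alternation: float = 0.5,
    max_press_inversion_ratio: float = 5.0,
) -> pd.DataFrame:
    """Apply the observer-exclusion rules, with reasons.

    An observer is excluded when, in the switch-relevant condition, fewer
    than half of their key presses indicated a direction change, or when, in
    the inversion-relevant condition, they pressed more than five times as
    often as inversions occurred (key spamming).  Exclusion applies to the
    observer as a whole.
    """
    rows = []
    for s in summaries:
        reason = ""
        exclude = False
        if s.condition == "switch_relevant":
            if np.isfinite(s.alternation_fraction) and s.alternation_fraction < min_alternation:
                exclude = True
                reason = (
                    f"alternation fraction {s.alternation_fraction:.2f} < "
                    f"{min_alternation} in switch-relevant condition"
                )
        elif s.condition == "inversion_relevant":
            ratio = s.press_to_inversion_ratio
            if np.isfinite(ratio) and ratio > max_press_inversion_ratio:
                exclude = True
                reason = (
                    f"press/inversion ratio {ratio:.2f} > "
                    f"{max_press_inversion_ratio} in inversion-relevant condition"
                )
        rows.append(
            {
                "observer": s.observer,
                "condition": s.condition,
                "exclude": exclude,
                "reason": reason,
            }
        )
    df = pd.DataFrame(rows, columns=["observer", "condition", "exclude", "reason"])
    excluded = set(df.loc[df["exclude"], "observer"])
    df["observer_excluded"] = df["observer"].isin(excluded)
    return df


def switch_rate_correlation(rates_a, rates_b) -> float:
    """Pearson correlation between paired per-observer switch rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance in rates")
    return float(stats.pearsonr(a, b).statistic)


def _direction_matches(switch_dir: str, anchor_dir: str) -> bool:
    # front-surface convention: OKN switch direction should equal the
    # direction reported by the press
    return switch_dir == anchor_dir


def peri_event_histogram(
    okn_switches: EventSeries,
    anchors: EventSeries,
    bin_ms: float = 250.0,
    window_s: tuple[float, float] = (-3.0, 1.5),
    split_matching: bool = True,
) -> pd.DataFrame:
    """Counts of OKN switches per lag bin relative to anchor events.

    Lag = switch time - anchor time, binned in ``bin_ms`` windows over
    ``window_s`` (half-open bins).  When ``split_matching`` is set and the
    anchors carry directions, counts are split by whether the switch
    direction matches the anchor's reported direction.  Counts are totals
    over all anchors; ``mean_per_anchor`` normalizes by the anchor count.
    """
    bw = bin_ms / 1000.0
    lo, hi = window_s
    edges = lo + np.arange(int(round((hi - lo) / bw)) + 1) * bw
    n_bins = len(edges) - 1
    match_counts = np.zeros(n_bins)
    nonmatch_counts = np.zeros(n_bins)
    n_anchors = len(anchors)
    for at, ad in zip(anchors.times, anchors.directions):
        lags = okn_switches.times - at
        in_win = (lags >= lo) & (lags < hi)
        if not in_win.any():
            continue
        idx = np.floor((lags[in_win] - lo) / bw).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        dirs = okn_switches.directions[in_win]
        for i, d in zip(idx, dirs):
            if split_matching and _direction_matches(d, ad):
                match_counts[i] += 1
            else:
                nonmatch_counts[i] += 1
    df = pd.DataFrame(
        {
            "bin_left_s": edges[:-1],
            "bin_right_s": edges[1:],
            "count_matching": match_counts,
            "count_nonmatching": nonmatch_counts,
        }
    )
    df["count_total"] = df["count_matching"] + df["count_nonmatching"]
    df["n_anchors"] = n_anchors
    df["mean_per_anchor"] = (
        df["count_total"] / n_anchors if n_anchors else np.nan
    )
    return df


def group_histogram(per_observer: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-observer mean (per anchor) and standard error per lag bin."""
    if not per_observer:
        raise ValueError("no per-observer histograms supplied")
    base = per_observer[0][["bin_left_s", "bin_right_s"]].copy()
    stacked = np.vstack([df["mean_per_anchor"].to_numpy() for df in per_observer])
    base["mean_per_anchor"] = stacked.mean(axis=0)
    base["sem"] = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
    base["n_observers"] = stacked.shape[0]
    return base


def switch_rate_per_min(switches: EventSeries, total_time_s: float) -> float:
    """Detected switches per minute of recording."""
    if total_time_s <= 0:
        raise ValueError("total time must be positive")
    return 60.0 * len(switches) / total_time_s
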