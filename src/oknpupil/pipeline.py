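"""End-to-end pipeline: preprocessing -> switch detection -> deconvolution ->
group cluster statistics -> validation/QC.

A configuration document (dict, or YAML/JSON path) either points at a session
directory on disk or carries a ``simulate`` block; the pipeline then runs
every stage per observer x condition and aggregates group-level statistics.
All outputs carry the configuration hash and seed, so a rerun with the same
document reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .cluster import ClusterTestResult, cluster_test, group_derivatives
from .deconv import deconvolve_trials
from .gaze import preprocess_gaze
from .pupil import preprocess_pupil
from .switches import detect_okn_switches
from .synth import Session, SimConfig, simulate_study
from .types import EventSeries, RecordingTrace, ResponseCurve
from .validation import (
    ObserverSummary,
    alternation_fraction,
    extract_manual_switches,
    group_histogram,
    peri_event_histogram,
    qc_exclude_observers,
    switch_rate_correlation,
    switch_rate_per_min,
)

DEFAULT_ANALYSIS = {
    "order": 6,
    "fs_fit": 50.0,
    "window": (-2.0, 6.0),
    "n_perm": 1000,
    "alpha_point": 0.01,
    "alpha_cluster": 0.01,
    "cos_thresh": 0.7,
    "win_ms": 1500.0,
    "step_ms": 38.0,
    "regressors": ("inversion", "okn_switch", "blink"),
    "task_order_filter": None,
}


@dataclass
class ConditionResult:
    """Everything the pipeline derives for one observer x condition."""

    observer: str
    condition: str
    okn_switches_by_trial: list[EventSeries]
    curves: dict[str, ResponseCurve]
    summary: ObserverSummary
    n_design_columns: int
    histogram: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    config: dict
    config_hash: str
    seed: int
    condition_results: list[ConditionResult]
    cluster_results: dict[tuple[str, str], ClusterTestResult]
    qc: pd.DataFrame
    rate_correlations: dict[str, float] = field(default_factory=dict)
    group_histograms: dict[str, pd.DataFrame] = field(default_factory=dict)

    def curves_frame(self) -> pd.DataFrame:
        frames = [
            c.to_frame()
            for r in self.condition_results
            for c in r.curves.values()
        ]
        return pd.concat(frames, ignore_index=True)


def _analysis_params(config: dict) -> dict:
    params = dict(DEFAULT_ANALYSIS)
    params.update(config.get("analysis", {}))
    return params


def process_observer_condition(
    observer: str,
    condition: str,
    trials: list[tuple[RecordingTrace, EventSeries]],
    params: dict,
) -> ConditionResult:
    """Run gaze cleaning, switch detection, pupil preprocessing, and
    deconvolution for one observer in one condition."""
    deconv_inputs = []
    okn_by_trial: list[EventSeries] = []
    presses_by_trial: list[EventSeries] = []
    total_time = 0.0
    n_inversions = 0
    for trace, events in trials:
        disp, _saccades, blinks = preprocess_gaze(trace)
        okn = detect_okn_switches(
            disp,
            win_ms=params["win_ms"],
            step_ms=params["step_ms"],
            cos_thresh=params["cos_thresh"],
        )
        ptrace = preprocess_pupil(trace, blinks)
        ev: dict[str, np.ndarray] = {}
        for reg in params["regressors"]:
            if reg == "okn_switch":
                ev[reg] = okn.times
            elif reg == "blink":
                ev[reg] = blinks.with_label("blink").starts
            else:
                ev[reg] = events.of_type(reg).times
        deconv_inputs.append((ptrace.t, ptrace.pupil, ev))
        okn_by_trial.append(okn)
        presses_by_trial.append(events.of_type("key_press"))
        n_inversions += len(events.of_type("inversion"))
        total_time += trace.duration
    curves = deconvolve_trials(
        deconv_inputs,
        order=params["order"],
        window=tuple(params["window"]),
        fs_fit=params["fs_fit"],
        observer=observer,
        condition=condition,
        event_types=tuple(params["regressors"]),
    )
    n_cols = len(params["regressors"]) * (2 * params["order"] + 1) + len(trials)

    all_presses = EventSeries.concat(
        [p.shifted(i * 1e6) for i, p in enumerate(presses_by_trial)]
    )  # large offsets keep per-trial press order without cross-trial pairs
    n_presses = len(all_presses)
    alt_frac = alternation_fraction(all_presses) if n_presses >= 2 else np.nan
    okn_count = sum(len(o) for o in okn_by_trial)
    manual_rate = np.nan
    if condition == "switch_relevant" and total_time > 0:
        manual_count = sum(
            len(extract_manual_switches(p)) if len(p) else 0
            for p in presses_by_trial
        )
        manual_rate = 60.0 * manual_count / total_time
    summary = ObserverSummary(
        observer=observer,
        condition=condition,
        manual_rate_per_min=manual_rate,
        okn_rate_per_min=60.0 * okn_count / total_time if total_time else np.nan,
        alternation_fraction=alt_frac,
        n_presses=n_presses,
        n_inversions=n_inversions,
    )

    # peri-event histogram: key-press anchored (switch-relevant) or
    # inversion anchored (the negative control)
    hist_frames = []
    for (trace, events), okn in zip(trials, okn_by_trial):
        if condition == "switch_relevant":
            anchors = (
                extract_manual_switches(events.of_type("key_press"))
                if len(events.of_type("key_press"))
                else EventSeries.empty()
            )
            split = True
        else:
            anchors = events.of_type("inversion")
            split = False
        if len(anchors):
            hist_frames.append(
                peri_event_histogram(okn, anchors, split_matching=split)
            )
    histogram = None
    if hist_frames:
        histogram = hist_frames[0][["bin_left_s", "bin_right_s"]].copy()
        for col in ("count_matching", "count_nonmatching", "count_total"):
            histogram[col] = np.sum([h[col].to_numpy() for h in hist_frames], axis=0)
        histogram["n_anchors"] = sum(h["n_anchors"].iloc[0] for h in hist_frames)
        histogram["mean_per_anchor"] = (
            histogram["count_total"] / histogram["n_anchors"]
        )
    return ConditionResult(
        observer=observer,
        condition=condition,
        okn_switches_by_trial=okn_by_trial,
        curves=curves,
        summary=summary,
        n_design_columns=n_cols,
        histogram=histogram,
    )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(text)
        return json.loads(text)
    return dict(config)


def _gather_trials(config: dict) -> tuple[dict[str, dict[str, list]], dict[str, str]]:
    """Return {observer: {condition: [(trace, events), ...]}} plus task-order
    tags, either from a simulate block or from a session directory."""
    task_order: dict[str, str] = {}
    if "simulate" in config:
        sim = dict(config["simulate"])
        n_obs = int(sim.pop("n_observers", 2))
        sim_cfg = SimConfig(**sim)
        sessions = simulate_study(sim_cfg, n_obs, seed=sim_cfg.seed)
        out: dict[str, dict[str, list]] = {}
        for i, (obs, session) in enumerate(sessions.items()):
            out[obs] = {
                cond: [(t.trace, t.events) for t in trials]
                for cond, trials in session.conditions.items()
            }
            task_order[obs] = (
                "switch_first" if i % 2 == 0 else "inversion_first"
            )
        return out, task_order
    data_dir = Path(config["data_dir"])
    out = {}
    for obs_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        obs = obs_dir.name
        out[obs] = {}
        for cond_dir in sorted(p for p in obs_dir.iterdir() if p.is_dir()):
            out[obs][cond_dir.name] = io_formats.read_session_trials(
                data_dir, obs, cond_dir.name
            )
        task_order[obs] = config.get("task_order", {}).get(obs, "")
    return out, task_order


def run_pipeline(config, output_dir=None) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Stages run per observer x condition, then group statistics pool across
    the observers that survive QC.  Any stage failure aborts with a message
    naming the stage.
    """
    config = _load_config(config)
    params = _analysis_params(config)
    seed = int(config.get("seed", 0))
    chash = io_formats.config_hash(config)

    try:
        trials_by_obs, task_order = _gather_trials(config)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: input] {exc}") from exc

    condition_results: list[ConditionResult] = []
    for obs, by_cond in trials_by_obs.items():
        for cond, trials in by_cond.items():
            try:
                res = process_observer_condition(obs, cond, trials, params)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"[stage: per-observer {obs}/{cond}] {exc}"
                ) from exc
            res.summary.task_order = task_order.get(obs, "")
            condition_results.append(res)

    try:
        qc = qc_exclude_observers([r.summary for r in condition_results])
        excluded = set(qc.loc[qc["observer_excluded"], "observer"])
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: qc] {exc}") from exc

    kept = [r for r in condition_results if r.observer not in excluded]
    order_filter = params.get("task_order_filter")
    pooled = [
        r
        for r in kept
        if order_filter is None or r.summary.task_order == order_filter
    ]

    cluster_results: dict[tuple[str, str], ClusterTestResult] = {}
    rng = np.random.default_rng(seed)
    try:
        conditions = sorted({r.condition for r in pooled})
        for cond in conditions:
            rs = [r for r in pooled if r.condition == cond]
            for etype in ("okn_switch", "inversion"):
                curves = [r.curves[etype] for r in rs if etype in r.curves]
                if len(curves) < 2:
                    continue
                group = group_derivatives(curves)
                cluster_results[(cond, etype)] = cluster_test(
                    group,
                    n_iter=params["n_perm"],
                    seed=int(rng.integers(0, 2**31 - 1)),
                    alpha_point=params["alpha_point"],
                    alpha_cluster=params["alpha_cluster"],
                )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: cluster-stats] {exc}") from exc

    rate_correlations: dict[str, float] = {}
    try:
        sw = [r for r in kept if r.condition == "switch_relevant"]
        if len(sw) >= 3:
            rate_correlations["okn_vs_manual"] = switch_rate_correlation(
                [r.summary.okn_rate_per_min for r in sw],
                [r.summary.manual_rate_per_min for r in sw],
            )
        by_obs = {r.observer: {} for r in kept}
        for r in kept:
            by_obs[r.observer][r.condition] = r.summary.okn_rate_per_min
        paired = [
            (v["switch_relevant"], v["inversion_relevant"])
            for v in by_obs.values()
            if len(v) == 2
        ]
        if len(paired) >= 3:
            rate_correlations["okn_between_conditions"] = switch_rate_correlation(
                [a for a, _ in paired], [b for _, b in paired]
            )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stage: validation] {exc}") from exc

    group_histograms: dict[str, pd.DataFrame] = {}
    for cond in sorted({r.condition for r in kept}):
        hists = [r.histogram for r in kept if r.condition == cond and r.histogram is not None]
        if hists:
            per_obs = []
            for h in hists:
                df = h[["bin_left_s", "bin_right_s", "mean_per_anchor"]].copy()
                per_obs.append(df)
            if len(per_obs) >= 2:
                group_histograms[cond] = group_histogram(per_obs)

    result = PipelineResult(
        config=config,
        config_hash=chash,
        seed=seed,
        condition_results=condition_results,
        cluster_results=cluster_results,
        qc=qc,
        rate_correlations=rate_correlations,
        group_histograms=group_histograms,
    )
    if output_dir is not None:
        write_results(result, output_dir)
    return result


def write_results(result: PipelineResult, output_dir) -> None:
    """Serialize the results bundle as CSV/JSON, stamped with config hash."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": result.config_hash, "seed": result.seed}

    curves = result.curves_frame()
    curves.insert(0, "config_hash", result.config_hash)
    curves.to_csv(out / "curves.csv", index=False, float_format="%.6g")

    rows = []
    for (cond, etype), ctr in result.cluster_results.items():
        df = ctr.to_frame()
        if df.empty:
            continue
        df.insert(0, "event_type", etype)
        df.insert(0, "condition", cond)
        rows.append(df)
    clusters = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["condition", "event_type", "start_s", "end_s", "sign", "mass", "p_mc", "significant"]
        )
    )
    clusters.insert(0, "config_hash", result.config_hash)
    clusters.to_csv(out / "clusters.csv", index=False, float_format="%.6g")

    qc_doc = {
        **meta,
        "exclusions": result.qc.to_dict("records"),
        "rate_correlations": result.rate_correlations,
        "summaries": [
            dataclasses.asdict(r.summary) for r in result.condition_results
        ],
    }
    with open(out / "qc.json", "w") as fh:
        json.dump(qc_doc, fh, indent=2, default=float)

    for cond, hist in result.group_histograms.items():
        h = hist.copy()
        h.insert(0, "config_hash", result.config_hash)
        h.to_csv(out / f"histogram_{cond}.csv", index=False, float_format="%.6g")

    with open(out / "run_meta.json", "w") as fh:
        json.dump({**meta, "config": result.config}, fh, indent=2, default=str)
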