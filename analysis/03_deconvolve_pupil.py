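"""Estimate event-related pupil responses by Fourier-basis deconvolution.

Runs the full per-observer chain on the shared cohort — gaze cleaning, OKN
switch detection, pupil interpolation and 15-s boxcar detrending, then the
three-regressor GLM (inversions, OKN switches, blinks) on the -2..+6 s
window — and writes the per-observer response curves plus the QC report.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import RESULTS_DIR, STUDY_CONFIG

from oknpupil.pipeline import run_pipeline, write_results


def main() -> None:
    # full per-observer bundle is bulky -> scratch; summary tables -> results
    result = run_pipeline(STUDY_CONFIG, output_dir=Path("scratch") / "pipeline")
    curves = result.curves_frame()
    group_mean = (
        curves.groupby(["condition", "event_type", "t_peri"])["value"]
        .agg(["mean", "sem"])
        .reset_index()
    )
    out = Path(RESULTS_DIR)
    out.mkdir(exist_ok=True)
    group_mean.to_csv(out / "group_curves.csv", index=False, float_format="%.5g")
    print(f"config hash {result.config_hash}, seed {result.seed}")
    print(
        f"fit {curves['observer'].nunique()} observers x "
        f"{curves['condition'].nunique()} conditions x "
        f"{curves['event_type'].nunique()} event types"
    )
    excluded = result.qc.loc[result.qc["exclude"], "observer"].unique()
    print(f"observers excluded by QC: {list(excluded) or 'none'}")
    for (cond, etype) in (("switch_relevant", "okn_switch"), ("inversion_relevant", "okn_switch")):
        sub = curves[(curves["condition"] == cond) & (curves["event_type"] == etype)]
        mean = sub.groupby("t_peri")["value"].mean()
        t_ext = mean.abs().idxmax()
        print(
            f"  {cond}/{etype}: group-mean extremum {mean[t_ext]:+.3f} mm "
            f"at {t_ext:+.2f} s"
        )
    print(
        f"group-mean curves in {RESULTS_DIR}/group_curves.csv; "
        "full per-observer bundle in scratch/pipeline/"
    )


if __name__ == "__main__":
    main()
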