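"""Test pupil-size change rate with the cluster-mass sign-flip permutation.

Reads the per-observer response curves written by 03_deconvolve_pupil.py,
takes per-observer temporal derivatives, and runs the cluster test
(pointwise one-sample t at p < 0.01, same-sign cluster mass, 1000 sign-flip
iterations, Monte Carlo p < 0.01) per condition x event type.  The expected
dissociation: dilation (positive derivative cluster) after task-relevant
switches, constriction (negative cluster) after ignored switches.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study import RESULTS_DIR, STUDY_CONFIG

from oknpupil.cluster import cluster_test, group_derivatives
from oknpupil.types import ResponseCurve


def main() -> None:
    curves_path = Path("scratch") / "pipeline" / "curves.csv"
    if not curves_path.exists():
        sys.exit("run analysis/03_deconvolve_pupil.py first")
    curves = pd.read_csv(curves_path)

    rng = np.random.default_rng(STUDY_CONFIG["seed"])
    rows = []
    for (cond, etype), sub in curves.groupby(["condition", "event_type"]):
        if etype == "blink":
            continue  # nuisance regressor, not a hypothesis
        per_obs = [
            ResponseCurve(
                g["t_peri"].to_numpy(),
                g["value"].to_numpy(),
                observer=obs,
                condition=cond,
                event_type=etype,
            )
            for obs, g in sub.groupby("observer")
        ]
        result = cluster_test(
            group_derivatives(per_obs),
            n_iter=STUDY_CONFIG["analysis"]["n_perm"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for c in result.clusters:
            rows.append(
                {
                    "condition": cond,
                    "event_type": etype,
                    "start_s": float(result.grid[c.start_idx]),
                    "end_s": float(result.grid[c.end_idx]),
                    "sign": c.sign,
                    "mass": c.mass,
                    "p_mc": c.p_mc,
                    "significant": c.p_mc < 0.01,
                }
            )
    table = pd.DataFrame(rows).sort_values(["condition", "event_type", "start_s"])
    out = Path(RESULTS_DIR) / "cluster_tests.csv"
    table.to_csv(out, index=False, float_format="%.4g")

    print(f"wrote {out}")
    for _, r in table[table["significant"]].iterrows():
        direction = "dilation" if r["sign"] > 0 else "constriction"
        print(
            f"  {r['condition']}/{r['event_type']}: {direction} rate cluster "
            f"{r['start_s']:+.2f}..{r['end_s']:+.2f} s, mass {r['mass']:.0f}, "
            f"p = {r['p_mc']:.3f}"
        )


if __name__ == "__main__":
    main()
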