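"""Simulate one example observer session and write it to disk.

Generates a two-condition session (switch-relevant / inversion-relevant)
with full ground truth, writes the tidy sample/event CSVs plus the
ground-truth JSON sidecar under scratch/example_session/, and prints what
was generated.  The larger cohort used by the later scripts is simulated
in memory from the shared seed (see analysis/study.py).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import STUDY_CONFIG

from oknpupil.io_formats import write_session
from oknpupil.synth import SimConfig, simulate_session


def main() -> None:
    sim = dict(STUDY_CONFIG["simulate"])
    sim.pop("n_observers", None)
    cfg = SimConfig(**sim)
    session = simulate_session(cfg, observer="example")
    out = Path("scratch/example_session")
    write_session(session, out)
    print(f"wrote example session to {out}/example/")
    for cond, trials in session.conditions.items():
        n_sw = sum(len(t.truth.switch_times_s) for t in trials)
        n_inv = sum(len(t.truth.inversion_times_s) for t in trials)
        n_blk = sum(len(t.truth.blink_intervals) for t in trials)
        n_rep = sum(len(t.truth.report_times_s) for t in trials)
        print(
            f"  {cond}: {len(trials)} trials, {n_sw} true switches, "
            f"{n_inv} inversions, {n_blk} blinks, {n_rep} key presses"
        )


if __name__ == "__main__":
    main()
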