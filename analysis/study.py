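"""Shared study definition for the analysis scripts.

One cohort of 8 simulated observers, two conditions (switch-relevant /
inversion-relevant), 2 trials x 90 s per condition at 500 Hz.  Every script
derives its inputs from this single seeded configuration, so the whole
analysis chain is reproducible end to end.
"""

STUDY_CONFIG = {
    "seed": 11,
    "simulate": {
        "n_observers": 8,
        "duration_s": 90.0,
        "n_trials": 2,
        "sample_rate_hz": 500.0,
        "seed": 11,
    },
    "analysis": {"n_perm": 1000},
}

RESULTS_DIR = "results"
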