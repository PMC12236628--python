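# oknpupil

Analysis pipeline for **no-report bistable perception**: when an observer
views an ambiguous structure-from-motion sphere, the perceived rotation
direction alternates spontaneously. Asking for reports makes every switch
task-relevant, so this pipeline instead reads the perceptual state from
**optokinetic nystagmus (OKN)** — the eyes' slow phases follow the perceived
front surface — and then asks how the **pupil** responds to switches that
the observer does or does not have to report.

It is aimed at visual-neuroscience / pupillometry researchers and provides,
as importable library code plus numbered analysis drivers:

1. **Synthetic sessions** (`oknpupil.synth`) — a generative model of the
   whole experiment (gamma-distributed dominance epochs, OKN sawtooth gaze,
   Poisson triangle inversions, blink artifacts, pupil traces built as exact
   kernel superpositions, delayed key-press reports) with full ground truth,
   so every stage below is testable by parameter recovery.
2. **Gaze preprocessing** (`oknpupil.gaze`) — Engbert–Kliegl velocity-threshold
   saccade detection (per eye, combined across eyes), pupil-slope blink
   detection, and the cleaned slow-phase displacement trace (artifact
   increments zeroed, blink buffers bridged).
3. **Switch detection** (`oknpupil.switches`) — 1500-ms sliding-window OLS
   slopes, gaze displacement angle, ±0.7 cosine classification, switches at
   midpoints between opposite percepts.
4. **Pupil deconvolution** (`oknpupil.pupil`, `oknpupil.deconv`) — blink
   interpolation, 15-s boxcar detrend, then a GLM in which each event type
   (inversions, OKN switches, blinks) has an impulse response on the
   −2..+6 s window expressed in a Fourier basis (constant + sine/cosine
   pairs):

   `y(t) = Σ_e Σ_k β_ek · f_k(t − t_e) + trial intercepts + ε`

5. **Cluster statistics** (`oknpupil.cluster`) — one-sample t per time point
   on the pupil change-rate curves, same-sign clusters with p < 0.01,
   cluster **mass** = Σ t, a 1000-iteration per-observer **sign-flip** null
   of the most extreme mass, and strict Monte Carlo p-values (significant at
   p < 0.01).
6. **Validation & QC** (`oknpupil.validation`) — manual-switch extraction
   from key presses, observer-exclusion rules, OKN-vs-manual rate
   correlations, and peri-event histograms (press-anchored, plus an
   inversion-anchored negative control).

`oknpupil.pipeline.run_pipeline(config)` chains all stages; tidy CSV/JSON
formats are defined in `oknpupil.io_formats`.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
8-observer cohort (2 conditions × 2 × 90-s trials, seed 11) and write their
tables under `results/`:

```bash
python analysis/01_simulate_session.py   # example session -> scratch/
python analysis/02_validate_okn.py
python analysis/03_deconvolve_pupil.py
python analysis/04_cluster_stats.py
python analysis/05_null_calibration.py
```

Output of `02_validate_okn.py`:

```
ground-truth switches recovered within +/-0.75 s: 324/333 (97.3%)
spurious OKN switches: 0.0000 per second
OKN-vs-manual switch-rate correlation (n=8): r = 0.96
OKN rate correlation between conditions: r = 0.92
peri-press histogram peak bin: [-1.00, -0.75) s relative to press
inversion-anchored control: max |deviation| from chance = 2.38 SE
```

The OKN read-out recovers 97% of ground-truth switches, observers who
switch fast by key press also switch fast by OKN, and OKN switches lead the
key presses by about a second — while showing no alignment with the
(independent) triangle inversions.

Output of `04_cluster_stats.py` (the headline dissociation):

```
  inversion_relevant/inversion: dilation rate cluster +0.12..+1.70 s, mass 1245, p = 0.005
  inversion_relevant/inversion: constriction rate cluster +1.82..+4.82 s, mass -2212, p = 0.000
  inversion_relevant/okn_switch: constriction rate cluster +0.22..+1.98 s, mass -1227, p = 0.008
  inversion_relevant/okn_switch: dilation rate cluster +2.12..+4.68 s, mass 1392, p = 0.001
  switch_relevant/okn_switch: dilation rate cluster +0.08..+1.68 s, mass 1280, p = 0.008
  switch_relevant/okn_switch: constriction rate cluster +1.82..+4.84 s, mass -2112, p = 0.006
```

Task-relevant events (switches when reported, inversions when reported)
produce a dilation — pupil size rises significantly for ~1.7 s after the
event, then falls back (the late negative-rate cluster is the return to
baseline). Ignored switches instead produce a constriction: a significant
negative change-rate cluster right after the switch. These are the injected
ground-truth kernels recovered end to end from raw simulated gaze and pupil
traces.

`05_null_calibration.py` checks the statistics themselves: on pure-noise
derivative curves the full cluster procedure declares a false positive in
about 1% of datasets or fewer, as the nominal p < 0.01 criterion demands.

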