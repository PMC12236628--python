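# Methods

`oknpupil` implements a no-report analysis of bistable perception: the
perceived rotation direction of an ambiguous structure-from-motion sphere is
read out from optokinetic nystagmus (OKN) instead of key presses, the pupil's
event-related response is estimated by linear deconvolution, and
pupil-size change rate is tested with a cluster-mass sign-flip permutation
procedure. Because the human recordings this kind of analysis targets are
not publicly distributable, the package ships a generative model of the
whole experiment; every stage is validated by parameter recovery against the
generator's ground truth.

## Generative model (synthetic sessions)

A simulated observer views the ambiguous sphere in two conditions —
*switch-relevant* (report perceived rotation reversals with left/right keys)
and *inversion-relevant* (report triangle-orientation inversions with
up/down keys). Per trial the generator draws:

* **Perceptual dominance.** Alternating left/right epochs with i.i.d.
  gamma-distributed durations (shape 3, mean 10 s by default). The gamma
  family is the standard description of dominance durations in bistability;
  shape ≈ 3 gives the usual right-skewed, non-exponential shape. Switches
  are the epoch boundaries.
* **Stimulus events.** The sphere rotates once per 6 s; each surface element
  follows a sinusoidal horizontal path and is relocated every 500 ms
  (limited lifetime). Triangle inversions form a Poisson stream with a 5-s
  mean interval. These three constants are the experiment's stimulus
  parameters and are fixed defaults.
* **OKN gaze.** During each epoch the eye drifts at the slow-phase gain
  (2 °/s) in the perceived direction; when eccentricity reaches the reset
  bound (3°) a 30-ms fast phase returns gaze to center. The resulting
  sawtooth is deterministic given the percept timeline; both eyes receive it
  plus independent Gaussian sensor noise (SD 0.02°, typical video-tracker
  precision at 1000 Hz). A stochastic trigger for fast phases would be more
  physiological but adds nothing the downstream algorithms are sensitive to.
* **Blinks.** A 0.2 Hz Poisson stream of occlusions: pupil ramps down 2 mm
  over 50 ms, stays occluded ~150 ms, ramps back over 100 ms; gaze is
  flagged invalid throughout. The ramp shape is the signature the blink
  detector keys on (rapid decrease, later rapid increase).
* **Pupil.** Baseline 4.5 mm plus a slow sinusoidal drift (0.15 mm,
  40-s period), plus an exact linear superposition of event-locked kernels,
  plus white noise (0.02 mm) and the blink artifacts. Kernels are
  unit-peak gamma densities parameterized by signed amplitude, peak latency,
  and shape, truncated to the −2..+6 s peri-event window. Defaults encode
  the task-relevance dissociation under study: task-relevant events
  (switches in the switch-relevant condition, inversions in the
  inversion-relevant condition) dilate the pupil by +0.2 mm peaking at
  1.75 s; ignored switches constrict it (−0.15 mm, peak 2 s); ignored
  inversions do nothing; blink onsets add a +0.15 mm recovery response.
* **Reports.** Each non-missed switch (miss probability 0.1) is followed by
  a key press after a truncated-normal delay (mean 1.0 s, SD 0.2 s),
  matching the observation that OKN-based switches lead key presses by
  0.75–1.5 s. The key encodes the post-switch direction.

Cohorts add between-observer heterogeneity: dominance means and kernel
amplitudes vary lognormally (SD 0.3 and 0.15 in log units), which is what
makes across-observer rate correlations informative.

All randomness flows from one integer seed through `numpy` `SeedSequence`
spawning, so sessions, studies, and the full pipeline are bit-reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mixed/transition percepts, smooth-pursuit
contamination and head motion, the pupil light reflex and gaze-angle
foreshortening, attention- or arousal-driven non-stationarity of kernels,
and report errors beyond simple misses. Recovery rates quoted by the tests
are upper bounds for clean, compliant observers.

## Gaze preprocessing

Saccades are detected per eye with the Engbert–Kliegl velocity-threshold
algorithm: 5-point moving-window differentiation, a median-based velocity SD
per axis, and an elliptic threshold at λ = 6 times that SD with a 6-ms
minimum duration. The two monocular interval sets are combined as their
union (the combination rule is a free choice; union is the conservative
one). The per-axis threshold is floored at 10 °/s: the median estimator
degenerates to zero on (nearly) noise-free constant-velocity drift, where a
bare multiplicative rule would flag everything; 10 °/s is far below saccadic
velocities and is inert at realistic noise, where 6·SD ≈ 40 °/s.

Blinks are read from the pupil trace: an onset where the 10-ms-smoothed
pupil change rate drops below −10 mm/s, an offset at the end of the next
run above +10 mm/s, with blinks closer than 100 ms merged and invalid runs
labeled `missing`.

The slow-phase displacement trace accumulates per-sample increments of the
binocular-average gaze position, with increments inside any
saccade/blink/missing interval set to exactly zero. Around each blink,
increments from 250 ms before to 400 ms after are replaced by the mean
increment over the 100-ms flanks just outside that buffer; the replacement
is applied to displacement *increments* (it precedes the angle computation,
and increments are the quantity the angle windows consume).

## Switch detection

A 1500-ms window stepped by 38 ms slides over the displacement trace;
per window, ordinary least-squares slopes of horizontal and vertical
displacement against time give the gaze displacement angle
(atan2(vertical slope, horizontal slope), full circle). Windows with
cos(angle) > +0.7 are labeled rightward, < −0.7 leftward, otherwise
unassigned; the inequalities are strict. A switch is marked at the
arithmetic midpoint of the centers of each pair of consecutive opposite
assigned windows, labeled with the new direction, so output directions
strictly alternate. Windows straddling trial edges are dropped rather than
shrunk (short fits are unstable); no minimum-duration filter is applied by
default (a debounce is available but off). The sliding fits use cumulative
sums (O(n) overall) with per-trace time re-centering to keep the closed-form
slopes exact to ~1e−10.

## Pupil preprocessing and deconvolution

Pupil size is linearly interpolated across blink/missing intervals padded by
100 ms (guarding eyelid-edge artifacts), then detrended by subtracting a
15-s centered sliding boxcar, truncated symmetrically at trial edges so the
output keeps the trace length. Trials shorter than the boxcar get their mean
subtracted, with a warning.

Event-related responses are estimated by a GLM: each of three regressors
(triangle inversions, OKN-based switches, blink onsets) is an unknown
impulse response on the −2..+6 s window expressed in a Fourier basis — a
constant plus `order` sine/cosine pairs (default order 6, 13 functions;
enough to express a kernel peaking at 1.5–2 s without ringing). The design
matrix places a time-shifted copy of the basis at every event, truncating at
trial boundaries, and appends one intercept per trial; trials are
concatenated. The signal is block-averaged to 50 Hz before fitting —
deconvolution is a smooth-curve estimation problem and gains nothing from
1000 Hz rows. Events are snapped to the nearest 20-ms sample (≤10 ms error,
well under the window step). Ordinary least squares solves the system;
rank-deficient designs fall back to the minimal-norm solution with a
warning. Multiplying coefficients back through the basis yields the
response curves.

## Cluster statistics

Inference runs on pupil-size *change rate*: each observer's curve is
differentiated (central differences; one-sided at the edges — the scheme is
a free numerical choice) before any averaging. Per time point a two-sided
one-sample t-test against zero is computed across observers; maximal runs of
consecutive points with p < 0.01 and a common derivative sign form clusters
scored by mass (sum of member t-scores). The null distribution of the most
extreme cluster mass comes from 1000 iterations in which each observer's
whole curve is sign-flipped with probability ½; each observed cluster's
Monte Carlo p is the strict proportion of null values more extreme, and
clusters with p < 0.01 are significant.

Two underdetermined details are resolved as follows and are configurable:
"most extreme" means largest absolute mass across both signs (a single
two-sided null, matching the two-sided pointwise tests), and "more extreme
than" is a strict inequality (conservative). Zero-variance time points are
assigned t = ±∞ (clamped internally) and flagged rather than silently
clustered. The permutation engine exploits the fact that sign-flipping rows
leaves per-column sums of squares unchanged, so all 1000 flipped t-maps
follow from one matrix product; run-scanning is vectorized across
iterations. A 1000-dataset × 1000-flip family-wise-error calibration
(24 observers × 81 points of i.i.d. N(0,1)) runs in seconds and lands at or
below the nominal 0.01 up to Monte Carlo error.

## Validation and QC

Manual switches are key presses whose direction differs from the previous
press (the first press is never a switch). Observers are excluded when
fewer than half of their switch-relevant presses indicate a direction
change, or when inversion-relevant presses exceed five times the inversion
count. OKN-vs-manual and between-condition switch-rate correlations are
Pearson correlations of per-observer rates (switches/min). Peri-event
histograms count OKN switches in 250-ms bins over a −3..+1.5 s window around
anchor events (key presses, or inversions as a negative control), split by
whether the switch direction matches the press under the front-surface
tracking convention; the window extent is a figure-scale choice and
configurable. All direction-changing presses serve as anchors. Task-order
subgrouping is a metadata filter (`task_order_filter`) feeding the same
deconvolution/statistics path, not a separate algorithm.

## Problem sizes

The simulator's default trial structure is 4 × 120-s trials per condition at
1000 Hz (trial counts and durations are not constrained by the underlying
experiment description; these are stand-ins). The worked example and the
`analysis/` scripts use a cohort of 8 observers × 2 trials × 90 s at 500 Hz
— enough observers for df = 7 group tests and enough events (~20 switches,
~35 inversions, ~30 blinks per condition) for stable kernel estimates, while
keeping a full run in the tens of seconds. The null calibration uses the
full 1000 × 1000 design.

## Known limitations

* The OKN read-out cannot distinguish front- from back-surface tracking;
  alternating surface tracking would create spurious switches that the
  generator does not model.
* With a 1500-ms window, switches closer than ~1.5 s apart can merge;
  the default gamma dominance parameters make such pairs rare.
* The boxcar detrend attenuates very-low-frequency components of the true
  kernels, so recovered curves can be offset/shrunk by ~10–20% of peak even
  when their shape correlates > 0.99 with ground truth; inference on the
  derivative is insensitive to the offset part.
* The blink detector assumes artifact slopes well above physiological pupil
  change rates; unusually slow eyelid movements would be missed.
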