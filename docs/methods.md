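# Methods

`patype` re-implements a physical-activity-type (PA-type) detection
pipeline that fuses multi-position accelerometry with GPS. It classifies
seven behaviors — walking, non-level walking (uphill/downhill/stairs),
running, cycling, sitting, standing, lying — from windows of wearable
sensor data, and is built around a synthetic-data generator so every stage
is testable without access to human-subject recordings.

## Study design emulated by the generator

A participant wears five tri-axial accelerometers (chest, left hip, right
hip, trouser pocket, right knee; 50 Hz) and one 1 Hz GPS receiver, and
performs annotated activity tasks in two protocols: a scripted
*semi-structured* session and a *real-life* session spanning an urban and a
leisure environment. Each task is bracketed by a
standing-still → jump → standing-still marker; the jump produces a high-g
transient on all five streams and is the basis for inter-device
synchronization. Devices are mounted with the y axis vertical; the
right-hip device is rotated so x is antero-posterior and z medio-lateral
(the others have x medio-lateral, z antero-posterior).

### Signal model

The accelerometer model is gravity + sum-of-harmonics + Gaussian noise.
It targets the feature families the classifier consumes (means, variances,
histograms, dominant frequencies), not biomechanical realism:

* **Postures** produce a quasi-static gravity vector with
  posture-and-position-specific orientation (sitting rotates thigh-mounted
  devices nearly horizontal; lying rotates all devices) and small
  micro-motion (standing sway > sitting fidgeting > lying).
* **Gait** adds harmonics of a subject-specific step frequency
  f0 ∈ [1.4, 2.2] Hz on the vertical and antero-posterior axes and a
  stride-rate sway on the medio-lateral axis. Amplitude scales with
  activity intensity (run > fast > normal > slow walk) and with position
  (knee 1.5× > pocket > hips > chest 0.8×). Running is modeled at 2·f0.
* **Cycling** is a cadence-locked (0.75·f0) pedaling signature, strongest
  at knee and pocket, plus 0.08 g broadband road vibration on all
  positions.
* **Non-level walking** matches level walking in amplitude and frequency
  almost exactly; its accelerometric cue is a small antero-posterior
  gravity shift from the incline lean (±0.087 g for a 10 % grade, less for
  stairs).

Subjects differ in step frequency, amplitude scale, preferred speeds,
sensor noise (0.03–0.08 g), harmonic shape, and a habitual
antero-posterior lean (sd 0.08 g, clipped at ±0.2 g). The habitual lean
deliberately masks the incline-lean cue *across* subjects while leaving it
consistent *within* a subject. This single knob reproduces the two
phenomena the package is designed to demonstrate: segment-wise k-fold
cross-validation is wildly optimistic relative to leave-one-subject-out
(L1SO) validation, and the GPS elevation feature — not the accelerometer —
is what reliably separates non-level from level walking across subjects.
The lean variability was calibrated once so that cross-subject
accelerometer-only confusion between the two walking classes is
substantial but bounded (general-model L1SO accuracy stays above 80 %);
it is the generator's central "separability knob".

### Terrain and GPS

Terrain is a DEM raster (default 2 m cells) in a planar local frame with
road polylines: a flat road and a ramp road (default grade 10 %).
Locomotion follows the appropriate road at the subject's preferred speed
(ping-pong at road ends; non-level walking traverses the ramp in the
direction the activity dictates, relocating along the ramp during the
unlabeled marker period when needed). Recorded fixes add horizontal
Gaussian noise (3–4 m leisure, 2× urban), speed noise (0.15 m/s), altitude
noise (1.5 m), and Poisson dropout gaps of 2–6 s (heavier in urban
blocks). Geometry is planar on purpose — geodesy is irrelevant to the
method — with a fixed equirectangular lat/lon shim for format
compatibility only.

### What the generator does not emulate

No biomechanically valid gait (no impact transients, no double-support
asymmetry), no multipath/satellite-geometry GPS error structure, no device
flipping in the pocket, no unannotated behavior between tasks. Passing
tests therefore show that the pipeline recovers the structure this model
encodes, not that the reported accuracies would transfer to human data.

## Preprocessing

1. **Cleaning**: drop rows with missing channels, sort, collapse duplicate
   timestamps (first occurrence wins).
2. **Synchronization**: detect total-acceleration peaks above 4 g
   separated by ≥ 1 s; shift each stream by the median peak-time
   difference to the chest reference. The 4 g default (rather than a lower
   threshold nearer the 3 g marker contract) keeps a margin above vigorous
   knee-mounted running, which can exceed 3 g; jumps are generated near
   6 g. Recovery error is sub-sample (≤ 20 ms) by construction of the
   shared transient.
3. **Annotation + trim**: label samples from the log, dropping 10 s at
   both ends of every row (the marker period); raw task labels map onto
   the seven grouped classes. Rows shorter than 2×trim are skipped.
4. **Stop removal**: within motion-labeled spans only, intervals where the
   1 s rolling sd of total acceleration stays below 0.05 g for ≥ 1 s are
   removed. Both parameters are free parameters of this implementation
   and are exposed in configuration.
5. **Windowing**: overlapping fixed-size windows (2–60 s; default 10 s,
   50 % overlap) advance by w·(1−overlap) within each task span. A window
   is emitted only if single-labeled and ≥ 95 % sample-complete; windows
   are half-open. The overlap fraction and the completeness tolerance are
   implementation choices (standard practice in the HAR literature; the
   segment-size sweep shows results are insensitive to windowing detail).

## Features

85 features per sensor per window — 61 time-domain, 24 frequency-domain —
over the four signals x, y, z and total acceleration ‖a‖:

* time: mean/sd/range (12), pairwise axis correlations (3), kurtosis and
  skewness of the axes (6), average absolute difference from the mean (4),
  10 fixed histogram bins per axis over a global ±3 g range (30), mean
  inter-peak interval and peak count per axis (6);
* frequency (on the demeaned window, plain FFT, no taper): mean
  one-sided periodogram over non-DC bins, spectral energy Σ|X_k|²/N
  (= N·variance by Parseval), the mean frequency of the three
  largest-magnitude non-DC bins, and those three amplitudes in descending
  order (ties → lower frequency), per signal.

The count arithmetic (61 + 24, with the average absolute difference
covering all four signals and the power spectral density taken as a scalar
summary) is shown in the README. Histogram bins use a fixed global range
so bin features are comparable across windows. Peaks are maxima above
mean + 0.5 sd with ≥ 0.2 s separation.

## GPS chain

clean → linear gap interpolation to a 1 Hz grid (gaps > 60 s left
unfilled; altitude of inserted fixes left null and recovered from the DEM)
→ point-to-curve map matching (nearest-point projection onto the nearest
road within 20 m; stationary fixes never snapped; no topological
continuity — this is the geometric category of map matching) → nearest-cell
DEM sampling → triangular-weighted smoothing (half-width 2, edges
renormalized). Per window: mean of reported instantaneous speeds, and
elevation difference = smoothed elevation at the last fix minus the first
(uphill positive, so the sign distinguishes up from down within the
non-level class; a sum-of-absolute-gains alternative was rejected because
it conflates the two). Windows with < 50 % GPS coverage get null features;
accelerometer-only models keep such rows, ACC+GPS models exclude them by
default (zero-imputation is available as a configured alternative — the
choice is logged).

## Classification and evaluation

Random forests (default 500 trees, √p features per split, fixed seed;
drivers pass 100 trees — see problem sizes below). Designs: *general* =
5 × 85 = 425 accelerometer columns; *individual* = 85; the two GPS
features are appended once (they are device-independent), giving 87 or 427
columns. Scenario 1 trains on semi-structured data, Scenario 2 on
semi-structured + real-life. Evaluation: L1SO (train on all other
subjects' scenario-training rows; test the held-out subject, on the
training protocols or on real-life rows; no held-out-subject data of any
protocol ever enters training, resolving the scenario-2 ambiguity in favor
of strict subject exclusion) and stratified segment-level k-fold, which
ignores subject identity and is included to demonstrate its optimism.

Metrics: per class one-vs-rest, precision over the predicted row, recall
over the true column, F1 = 2pr/(β²p + r) with β = 1 (the general F-β form
with a fixed 2× numerator reduces to standard F1 at β = 1, which exactly
reproduces the published worked-example tables bundled in
`patype.worked_examples`); overall accuracy = trace/total. Reports round
half-up to integer percentages for display and keep full precision
internally. The confusion-matrix orientation (rows = predicted) is pinned
by a regression test against those worked examples.

## Problem sizes and numerical choices

The study drivers in `patype.experiments` run five independent replicates
of a 10-subject cohort (two protocols × ten 60 s tasks each, 10 s windows,
100-tree forests), a 20-trial synchronization-recovery check, a ramp-grade
recovery on a 120 s uphill walk, and a 4-subject semi-structured
segment-size sweep over {2, 5, 10, 20, 30, 60} s. These sizes characterize
the pipeline well on a single CPU; cohort size, task durations, tree
counts and window sizes are all parameters.

Degenerate inputs: zero-variance axes yield correlation/kurtosis/skewness
of 0 (flagged by convention); fewer than three non-DC spectral bins pad
the dominant-frequency slots with zeros; empty streams and single-class
training labels raise. All randomness flows from a single master seed
through `numpy` SeedSequence spawning (per-subject, per-block, per-stage
child seeds), so every artifact is byte-reproducible given its seed.

## Known limitations

* The generator's class structure is easier than human data everywhere
  except the walking/non-level boundary, which is calibrated to be hard;
  absolute accuracies are therefore not comparable to field studies.
* Map matching is memoryless point-to-curve; dense road networks would
  need topological matching.
* The GPS features assume outdoor, road-following motion, as does the
  source method.
* No orientation auto-correction for flipped or rotated devices.
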