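# Methods

This note documents the models, conventions and design choices behind
`sipsense`: what the synthetic generator emulates, how each pipeline stage is
defined where the field leaves room, and what the package's results do and do
not show about real recordings.

## The synthetic drinking-session generator

The generator replaces unavailable human recordings. It emulates a
controlled protocol: each participant performs every combination of fill
level and sip size a fixed number of times (defaults: 12 participants,
fill levels 100–400 g in 50 g steps in a 500 g cup, sip sizes
small/medium/large, 4 repetitions, 128 Hz sampling, sensor ranges ±16 g and
±2000 deg/s), and each event is the strict gesture sequence
grasp → pre-sip → sip → post-sip → release.

**Axis and gravity convention.** The container sensor's +Z axis points up
when the cup rests on the table, so the resting accelerometer reads
(0, 0, 1) g. The sip tilt is a rotation about the sensor X axis by θ(t), so
gravity appears as (0, sin θ, cos θ) and the Z-axis inclination equals θ.

**Couplings built in (and why).** These are the causal structure the
downstream analysis assumes; each is a modeling commitment, not a fitted
quantity:

* *Sip amount* A ~ truncated normal per category (large 53.82 ± 8.58 g,
  medium 27.23 ± 6.20 g, small 10.71 ± 5.56 g; floor 1 g by rejection
  sampling, upper bound the fill level).
* *Sip duration* d = (0.6 + 0.35·A^0.6)·pf + ε, with a per-participant rate
  factor pf ~ N(1, 0.06) and trial noise ε ~ N(0, 0.1 s), floored at 0.5 s.
  The law is concave and strictly increasing in A: longer sips mean larger
  amounts, but the amount-per-second grows with sip size, which is what
  gives per-category regressors a genuine local-slope advantage over one
  global model. Other phase durations are uniform (grasp/release 0.5–1.5 s,
  pre/post-sip 1–2 s); no durations are available from real data.
* *Peak sip tilt* θ̂ = 35° + 55°·(1 − fill/capacity) + participant habit
  (SD 3°) + trial noise (SD 4°): an emptier cup must be tipped further, so
  tilt features carry the fill-level signal. During pre-/post-sip the cup is
  carried at 15°; the sip tilt follows a half-sine bump between carry and
  peak. Lift and lower contribute opposite-signed vertical acceleration
  bumps (±0.25 g), which is what makes pre-sip and post-sip separable.
* *Container at rest outside pre-sip…post-sip*: gravity plus sensor noise
  only (acc SD 0.01 g, gyro SD 1 deg/s).
* *Wrist = container motion seen badly.* The wrist stream is the container's
  motion rotated by a constant per-participant orientation offset (uniform
  ±15° about X and Y), plus wrist-only reach/retract gyro bursts in
  grasp/release (±80 deg/s half-sines, opposite signs, with ±0.3 g
  accelerometer wiggle), plus a slow orientation wobble (small-angle
  rotations interpolated from 4 Hz Gaussian nodes of SD 4° — a hand is never
  rigid the way a cup is), plus white noise at 3× the container's SD. The
  reach/retract motion exists because the container is stationary during
  grasp and release: without wrist-specific motion those two classes would
  be statistically identical and the wrist arm could not see its five
  phases. The offset and wobble are what make the wrist arm genuinely
  harder: LOSO cannot calibrate a held-out participant's offset, and the
  wobble corrupts inclination features.

Signals are quantized to 1e-7 at generation, so the plain-text session
bundle (one CSV per sensor stream, `%.7f`; one JSON metadata file per
event; versioned manifest) round-trips exactly and identical seeds give
byte-identical files.

**What the generator does not emulate.** Arm kinematics are schematic (no
biomechanics, no liquid sloshing, no translation-induced specific forces
beyond the lift bumps), there are no non-drinking confounders, label
boundaries are exact rather than video-annotated, and noise is Gaussian and
stationary. Consequently, absolute performance numbers on synthetic data are
optimistic and are not comparable to numbers measured on human cohorts; what
the tests establish are the *relative* directions that follow from the
built-in couplings (container arm cleaner than wrist arm, size-dependent
models beating general ones, recognition errors degrading volume
estimation), plus exact correctness of every deterministic computation.

## Derived channels

Angular acceleration is the central finite difference of the gyroscope
(one-sided at the ends) scaled by the sample rate. Inclination is defined
per axis against the instantaneous acceleration direction,
θᵢ = arccos(aᵢ/‖a‖) in degrees, with ‖a‖ = 0 mapped to 90° per axis; no
orientation filter is used, so the channel is computable from raw samples
alone and is invariant to uniform rescaling of the acceleration vector.
During quasi-static tilts the acceleration direction is the gravity
direction and θ_z equals the tilt angle.

## Windowing and window ground truth

Window/overlap grid: {16, 24, 32, 40, 48, 56} samples ×
{25, 50, 75, 87.5} %; every combination yields an integer step and the step
is validated. Trailing partial windows are dropped, not padded. A window's
ground-truth label is the majority of its per-sample labels; ties go to the
label whose run starts earlier in the window.

## Gesture features and classifier

96 features = 8 statistics × 12 channels, stored stat-major (all channels
for the mean, then for the SD, …). Skewness and kurtosis use population
(biased) moment ratios; kurtosis is non-excess (Gaussian → 3); windows with
variance below 1e-12 set both to 0 so constant windows never produce NaNs.
The classifier is an RBF-kernel SVM with C = 1 and kernel width
1/(n_features · feature variance), one-vs-one decisions, preceded by
per-training-fold standardization. Hyperparameters are fixed in the spec
object, never tuned per fold. Training windows per LOSO fold are capped at
2000 by a seeded class-proportional subsample — kernel-SVM cost grows
superlinearly and the full folds hold ~50k windows; prediction always covers
every test window. The container arm is windowed over the event's
pre-sip…post-sip span only (the container does not move outside it), which
mirrors how activities were manually extracted in the original setting; its
label set is {pre-sip, sip, post-sip}.

## Postprocessing

The correction rule rewrites an interior run of one or two windows to the
preceding fragment's label when the fragments immediately before and after
the run agree. The scan is sequential left-to-right and corrections are
visible to later positions, so cascades are allowed
(A B A B A → A A A A A); runs touching either sequence end are never
modified. The operation is idempotent; the test suite proves equivalence
with a position-by-position brute-force implementation exhaustively for all
3-label sequences up to length 8.

## From window labels to segments

Contiguous equal-label window runs are merged; the boundary between two
runs is the midpoint of the adjacent windows' centers, the first run starts
at the first window's start and the last ends at the last window's end. If
several sip runs survive postprocessing the longest is kept (first on
ties); the nearest preceding pre-sip run and nearest following post-sip run
complete the triple. Events with no recognized sip run are flagged,
excluded from volume metrics, and reported as a count.

## Volume and fill-level features

From a sample interval [lo, hi): duration (hi−lo)/fs; per-direction average,
maximum and integral of inclination; counts of samples with inclination
strictly over k° (k = 10…90°) and strictly over p % of the interval's own
per-direction maximum (p = 10…90 %; a zero maximum yields zero counts).
Counts are raw sample counts (convertible to seconds by dividing by the
sample rate). The integral is the trapezoidal rule extended half a sample at
each end (equivalently sum × Δt on the uniform grid), so a constant θ over
duration T integrates to θ·T — keeping the integral consistent with the
duration feature. The normalized-threshold denominator is interval-local,
making the feature self-contained under recognized (possibly shifted)
boundaries. With the fill level appended the vector has 65 entries, else 64.

Fill-level estimation uses the same 64 features computed over the
pre-sip…post-sip interval (recognized boundaries, matching how it would be
deployed), with SVR; volume estimation uses the sip interval. SVR settings:
ε = 1 g, C = 10, Gaussian width as in the classifier; features are
standardized per training fold; targets stay in grams. The linear kernel is
solved by liblinear (seeded) rather than the kernelized solver — the same
model, orders of magnitude faster at this size.

Sip-size-dependent models train one SVR per category present in the
training fold and route each test event by its ground-truth category;
category prediction at test time is out of scope and flagged here as the
known idealization. In the segment-source study, true segments pair with
true fill levels and recognized segments with LOSO-estimated fill levels
(the deployable combination); the estimated-fill feature uses each event's
out-of-fold estimate.

## Evaluation

LOSO folds hold out one participant completely; partitions are exhaustive
and disjoint. Sensitivity, precision and F1 are macro-averaged one-vs-rest
(the F1 is the harmonic mean of macro sensitivity and macro precision);
micro-averaged variants are reported alongside since the averaging scheme
is a genuine ambiguity. Classes absent from both truth and prediction are
excluded from the macro average. Grid-study best cells are chosen by
accuracy, ties broken toward the smaller window then the smaller overlap.
The general-vs-size-dependent contrast compares each family's best result
across the linear and Gaussian kernels.

Problem sizes: the standard study runs the full 1008-event protocol; unit
and integration tests use reduced grids (27 events, 1–2 grid cells) chosen
as the smallest sizes at which each property is meaningful.

## Known limitations

* Ground-truth sip-size dispatch for size-dependent models (above).
* The container arm consumes ground-truth activity extents
  (pre-sip…post-sip span) for windowing.
* The fill-level feature used in training the "estimated fill" combination
  is the event's out-of-fold estimate, i.e. estimates for training events
  come from folds in which they were test items.
* Synthetic-data caveats listed under the generator section: directions,
  not absolute magnitudes, transfer to real data.
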