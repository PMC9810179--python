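# Methods

## The task and the analysis it feeds

The vestibular rotation task probes path integration from vestibular cues
alone: a blindfolded, ear-plugged participant seated in a rotating chair is
turned through a scripted sequence of one to three rotations and, after a
3 s delay, points a hand-held tablet back at a remembered reference object
(e.g. the room's door).  Only the pointing-back response is recorded: the
tablet's accelerometer (m/s²), gyroscope and compass stream at a 0.003 s
sample period along device axes x (forward/backward), y (left/right) and
z (up/down).  Nine trials of increasing complexity are administered; the
fixed rotation sequences live in `vrtask.protocol` (trial 1 = +90° up to
trial 9 = −200°, +310°, −190°; clockwise positive).  Because each trial is
a different rotational movement, trials are analysed separately and never
pooled.

The analysis asks whether movement phenotype separates a genetic-risk
group (APOE ε3ε4 carriers) from matched ε3ε3 controls in a cohort of
53 participants (32 ε3ε3, 21 ε3ε4, mean age ≈ 63).

## Synthetic cohorts

No participant recordings are publicly available, so `vrtask.simulate` is a
first-class generator, not a test fixture.  Its defaults are the study
conditions; everything is reproducible from one seed.

**Response kinematics.**  The device heading starts at the post-rotation
body heading (reference bearing minus the trial's net rotation, wrapped)
and follows a minimum-jerk angular trajectory (s(τ) = 10τ³ − 15τ⁴ + 6τ⁵)
along the minimal arc to the reference bearing plus a Normal(bias, sd)
pointing error.  A Poisson-distributed number of hesitations is inserted as
0.35 s pauses (angular velocity ≈ 0), capped at 3 and so that ≥ 0.5 s of
motion remains; pause times and counts are stored as ground truth.  Linear
acceleration is modelled as the tangential plus centripetal acceleration of
a hand-held arc of lever arm 0.35 m, scaled by the participant's
`jerk_scale`; the vertical axis carries +g = 9.81 m/s².  Gyroscope channels
are emitted as per-sample angular increments in degrees (rate × 0.003 s),
which makes the downstream tilt/rate-of-change feature units literal
degrees; off-axis channels carry white "tilt wobble".  The compass channel
is wrapped to [0, 360), so genuine wraparound discontinuities occur
whenever the trajectory crosses north, and carries low-pass-filtered jitter
(SD 0.3°).  With probability `flip_prob` (default 0.05) the whole stream is
emitted in the 180°-flipped device frame (compass + 180°, y/z axes of both
inertial sensors inverted) — the artifact the preprocessing must undo.

**Latent phenotypes.**  Each participant draws a phenotype from
group-specific distributions: Gamma (shape 25, CV 20%, mean exact) for the
non-negative scale parameters, Normal for the pointing bias.  Baseline
(ε3ε3) means: pointing-error SD 10°, bias 0°, hesitation rate 0.5/trial,
jerk scale 1.0, tilt wobble 0.02°/sample, duration 2.0 s.  The risk-group
deltas — +8° error SD, +1.0 hesitations/trial, +0.5 jerk scale — are all
multiplied by a single `effect_size`; 0 gives a fully null cohort and the
group-mean separation scales linearly.  The choice to place the effect
jointly on accuracy, hesitancy and movement vigor reflects the construct
the task targets (vestibular path-integration deficit expressing as less
accurate, less fluent pointing); individual deltas are configurable so
feature-importance behaviour can be probed per feature.  Demographics
(age means 63.6/63.0, male fractions 17/32 and 6/21) are group-matched
nuisance variables; their group differences are also scaled by
`effect_size` so the null cohort is demographically null too.  Durations
are floored at 2.0 s because the 1.0 s jerk feature needs two complete
blocks.

**What the generator does not emulate:** the chair-rotation phase (not
recorded by the device), biomechanically faithful arm/torso dynamics,
magnetometer calibration error, drift or temperature effects, and any
within-session learning or fatigue.  Passing tests therefore demonstrate
that the pipeline recovers structure *of this kind* at study scale — not
that real tablet data contain that structure.

## Preprocessing

* **Flip correction** — a stream is declared flipped when the median
  gravity-axis (z) accelerometer reading is negative (flat-held expectation
  +g; the median is robust to movement transients).  The correction is the
  involutive device-frame rotation, so it is idempotent and recovers the
  unflipped emission to < 1e-9.
* **Compass unwrapping, 80° gate** — successive compass differences above
  80° are wrap-corrected by the nearest multiple of 360°; if the corrected
  difference still exceeds the gate the sample is rejected as a glitch,
  linearly interpolated, and counted.  Wrap-first-reject-fallback puts both
  plausible readings of a bare "80° threshold" behind one gate, and the
  flags record which fired.
* **Smoothing** — centered 100-sample moving average, edges truncated
  (window covers 50 left / 49 right samples).  Centered rather than causal
  because causal filtering would lag hesitation locations by ~0.15 s.
* **Peak detection** — SciPy `find_peaks` on the smoothed series and its
  negation with a prominence floor of 5% of the dynamic range, merged into
  a strictly alternating peak/trough sequence (ties keep the more extreme,
  then earlier, event).

## Features (27 per trial response)

End error (minimal circular distance final-heading → reference, [0, 180]°);
total angular displacement (Σ|Δ| of the unwrapped heading); per-axis tilt
(largest-magnitude gyro sample, sign kept); gyroscopic rate of change
(block averages over 0.1/0.5/1.0 s windows, averaged across blocks, per
axis); per-axis mean acceleration; jerk (differences of successive block
sums over the same three windows, divided by the window length; mean of
absolute differences by default — a signed mean cancels on back-and-forth
movement; `jerk_mode="signed"` is available); and the hesitation count.

Numerical choices worth noting:

* The 0.1/0.5/1.0 s windows are not whole multiples of the 0.003 s period;
  blocks are realised as the nearest sample count (33/167/333, within 1% of
  nominal) and a > 2% mismatch is rejected.
* Hesitation detection runs on the Euclidean norm of *gravity-removed*
  (per-axis median-subtracted) acceleration: with +g riding on z the raw
  norm never approaches zero and no stop could ever register.  A trough
  counts as a stop below 10% of the smoothed trace's 95th percentile
  (configurable).
* "Changes in compass points" are degrees of heading, not 32-point compass
  sectors; the displacement unit is degrees.
* An optional pairwise-correlation filter (drop one of any pair with
  |r| > 0.95) is provided but disabled by default.

Degenerate inputs raise `ValueError` (empty channels, traces shorter than
one/two blocks, single-sample heading series); a flat series yields zero
events rather than an error.

## Classification

Per trial table: the 27 features, plus age (standardised), sex (male
indicator) and occupation (one-hot) unless the feature set excludes them.
Feature sets: `all`, `no_end_error` (movement-only), `no_demographics`.
Algorithms: random forest (100 trees, standard defaults), SVM over
C ∈ {0.5, 1, 3, 5, 10, 20} × {linear, rbf}, and an MLP over
α ∈ {0.0001, 0.0005, 0.001, 0.002}.  Outer CV is stratified 5-fold; the
fold builder deals the larger class first and sends surplus members to the
smallest folds, giving sizes {11, 11, 11, 10, 10} for 32/21 with 6–7
controls and 4–5 carriers per fold.  Standardisation statistics come from
training folds only.

Hyperparameter selection is nested by default (inner stratified 3-fold on
each training portion), which keeps selection out of the reported score; a
non-nested "naive" mode (one grid point chosen by its outer-CV mean) exists
for comparison and for Monte-Carlo studies where its 3× lower cost matters.
F1 uses the positive class ε3ε4: TP / (TP + 0.5 (FP + FN)); accuracy is the
fraction correct.  Chance level is calibrated empirically by label
permutation — the commonly quoted single-number chance constant for this
split is not derivable from 32/21 under any standard convention, so the
package never assumes it.

Importances: impurity-based for RF; held-out permutation importance under
F1 (10 repeats) for SVM/MLP; averaged over folds, clipped at zero,
normalised to sum to 1 (uniform with a warning if identically zero).

All randomness (folds, model seeds, permutation repeats) derives from one
master seed through documented per-fold seed sequences; identical inputs
and seed give bit-identical results.

## Validation problem sizes

The statistical acceptance tests run at deliberately chosen scales: oracle
equivalence on 500 random ~700-sample streams; null calibration on one
full 32/21 zero-effect cohort against a 120-permutation best-of-three-
algorithms band computed from one trial's table (under the null all trials
are exchangeable draws from the same generator, so one band serves all
nine); effect-size monotonicity over effect ∈ {0, 0.5, 1, 2} × 10 seeds
with the reduced grid (C ∈ {1, 10}, α ∈ {0.0001, 0.001}, 60 trees, 25-unit
MLP) and naive selection; hesitation recovery on 200 default-noise streams.
The reduced grid and naive mode are used consistently for both the
observed values and their permutation reference, so the calibration
comparison is like-for-like.

## Known limitations

* The simulator's group effect is, by construction, detectable by the
  features the pipeline extracts; it demonstrates parameter recovery, not
  clinical validity.
* Flip detection assumes a roughly flat-held device; a device held
  vertically for most of a response would defeat the gravity-sign
  criterion.
* The minimum-jerk trajectory is smoother than real pointing; jerk
  features on synthetic data are dominated by the hesitation/vigor
  structure the generator injects.
* With heading noise enabled, total angular displacement accumulates a
  noise floor (Σ|Δ| of jitter); group contrasts on displacement therefore
  ride on that floor exactly as they would on a real compass.
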