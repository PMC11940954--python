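# Methods

This note documents the models, conventions, and numerical choices behind
`infantmotion`, in the order the pipeline runs, and states what the
synthetic-data experiments can and cannot show.

## Input model and cleaning

A recording is a sequence of 17-keypoint skeletons in the COCO order, one
per frame at a fixed frame rate (nominally 15 fps), each keypoint carrying a
detector confidence in [0, 1]. Coordinates are 0-based pixels, origin
top-left, y down. Keypoints with confidence strictly below the threshold
(default 0.5; equality is kept) are treated as missing, and missing samples
are filled by per-track linear interpolation between the nearest visible
neighbours. Leading/trailing gaps take the nearest visible value rather
than extrapolating — extrapolation would manufacture motion at clip
boundaries. Interpolated samples are marked visible with confidence equal
to the filtering threshold, recording that they are reconstructions at the
acceptance boundary. A track that is never visible cannot be reconstructed;
the sequence is excluded (and listed in the run report) rather than
zero-filled, because a fabricated static joint would bias every speed
feature downward and mimic the hypokinetic signature the classifier looks
for.

## Smoothing and normalization

Per-frame pose estimation jitters; a centered rolling mean of 5 frames
(~0.33 s at 15 fps) suppresses it. The window must be odd (no phase lag)
and is truncated symmetrically at the sequence ends so no frames are lost
and a 15 s clip stays exactly 225 frames. Note the filter is low-pass: at
15 fps it passes ~1–1.5 Hz limb oscillation largely intact but strongly
attenuates components above ~2.5 Hz; measured speeds are speeds of the
smoothed skeleton, as intended.

Normalization maps each frame into a body-anchored frame: translate the
shoulder midpoint to the origin, rotate the trunk vector (shoulder midpoint
→ hip midpoint) onto +y, divide by that frame's trunk length. The rotation
is proper (determinant +1), so left/right laterality is preserved. Rotation
is applied per frame; smoothing precedes normalization (in pixel space) so
that rotation jitter is not amplified before filtering. After this step all
coordinates are in trunk lengths and every downstream feature is invariant
to global translation, rotation, and uniform scaling of the raw pixels
(verified to ≤ 1e-6 over random similarity transforms). A frame with zero
trunk length is degenerate and rejected.

## Clips and the activity gate

Sequences are cut into consecutive, non-overlapping clips of
`round(15 s × fps)` frames from the start; a shorter trailing remainder is
dropped, not padded. The activity score of a clip is the mean instantaneous
speed of the 8 distal joints (elbows, wrists, knees, ankles) — forward
differences times fps, with the last frame copying its predecessor so the
series has one value per frame; this scheme reproduces constant-velocity
cases exactly. Shoulders and hips anchor the normalized frame and move
little by construction, so they are excluded from the score. Clips qualify
when the score strictly exceeds 0.9 trunk lengths/s; only qualifying clips
are assessed, i.e. the classifier sees awake, actively moving behaviour.

## The 227-feature catalog

The catalog is fixed and normative for this package: every clip maps to the
same 227 named scalars, in blocks of

| block | count |
|---|---|
| distal speed mean + max | 16 |
| distal acceleration mean + max | 16 |
| distal speed entropy | 8 |
| distal acceleration entropy | 8 |
| distal segment angular velocity mean + max | 16 |
| distal segment angular acceleration mean + max | 16 |
| 8 joint angles × {mean, max, min, std, range} | 40 |
| 8 joint angular velocities × {mean, max, std} | 24 |
| 8 joint angular accelerations × {mean, max, std} | 24 |
| C(8,2) joint pairs × {speed, acceleration} windowed correlation | 56 |
| whole-body mean speed, mean acceleration, speed entropy | 3 |

Conventions that needed deciding:

- **Joint angles** (degrees, [0, 180]): elbow/knee are the interior angle
  between the adjoining segments (180° = extended); shoulder/hip are
  measured against the caudal trunk direction, giving a fixed, reproducible
  sign-free convention. A zero-length ray (coincident keypoints) carries
  the previous frame's angle forward.
- **Distal angular kinematics**: wrists and ankles terminate the chain and
  have no interior angle, so they carry the orientation-angle rate of the
  segment that ends at them (forearm, shank; elbow/knee analogously use
  upper arm/thigh). Orientations are unwrapped before differencing.
  Magnitudes (absolute values) are used for mean/max/std, matching the
  speed features' semantics.
- **Windowed correlation**: Pearson correlation on every sliding 5-frame
  window, averaged over windows; windows where either series is constant
  are skipped, and an all-skipped pair scores 0. "Constant" uses an
  absolute standard-deviation floor of 1e-8 trunk lengths/s: the anchor
  joints are static in the normalized frame up to floating-point residue of
  the rolling-mean filter, and correlating that residue would make the
  feature depend on camera placement. With window = series length the
  statistic equals the plain whole-series Pearson correlation.
- **Entropy**: Shannon entropy (nats) over 10 equal-width bins spanning the
  series' own [min, max]; scale-free, deterministic, 0 for constant series,
  at most ln 10.

All features are finite by construction; degenerate statistics resolve as
above rather than to NaN.

## Screening and classification

Per-feature one-way ANOVA across the two label groups retains features with
p < 0.05 (no multiple-testing correction, matching the protocol being
reproduced; a Benjamini–Hochberg-adjusted selection is reported alongside
as supplementary output). For two groups, F is identically the squared
pooled-variance two-sample t statistic, which the tests exploit as an
oracle. Degenerate columns are resolved explicitly: zero between-group
variance → F = 0 (never selected); zero within-group variance with distinct
means → p = 0 (always selected).

The minority class is oversampled to a target count (default 3× the
minority size, so 26 delayed clips become 78) by whole-set replication plus
a seeded remainder draw without replacement — an integer-multiple target is
exact replication, and the result is deterministic under the seed. Features
are then standardized to zero mean and unit variance (population variance;
zero-variance columns map to 0), and four classifiers — random forest,
XGBoost, SVM, logistic regression, each with its library's default
hyperparameters, recorded verbatim in the report — are evaluated by
seeded stratified k-fold cross-validation (default 5 folds). Reported
metrics are accuracy, recall, precision, F1 and AUC, support-weighted over
classes within a fold and support-weighted over folds (macro averages are
reported alongside). For a binary task the one-vs-rest AUC is identical for
both classes, so the weighted AUC equals the plain AUC of the
positive-class score.

**Execution order.** The default order screens, oversamples and
standardizes on the full table *before* cross-validation, reproducing the
protocol this package models. That order leaks: duplicated minority rows
straddle folds and held-out rows influence selection and scaling, so its
metrics are optimistic. The `leakage_safe` flag instead fits all three
steps inside each training fold. Both modes are first-class; calibration
claims (below) use the leakage-safe mode, reproduction uses the default.

## Keypoint evaluation

OKS is the visibility-masked mean of exp(−dᵢ²/(2 s² kᵢ²)). The per-keypoint
constants default to twice the canonical MS-COCO sigmas (the COCO
evaluation convention). The object scale s defaults to the square root of
the annotated bounding-box area; a literal "area" convention is also
supported via `object_scale_from_area`, and the CLI records which
convention produced a number. Matching is 1:1 (one infant per image), so at
each threshold a case is simply hit or missed and per-threshold precision
equals recall; mAP and mAR are the means over thresholds 0.50 : 0.05 : 0.95
and coincide in this regime.

## The motion simulator

The generator models a supine infant filmed from above as a planar
kinematic chain with trunk length 1: fixed head/trunk anchor points, limb
segments (upper arm 0.45, forearm 0.40, thigh 0.50, shank 0.45 trunk
lengths) whose orientation angles follow seeded sums of sinusoids
(fundamental + 0.4-weight harmonic at 1.7× the frequency, random phases).
Per-subject log-normal jitter (σ = 0.12) on amplitudes and frequencies
makes features vary within class. A slow rigid whole-body wobble, a random
per-subject camera transform (rotation, pixel scale 120–250 px/trunk,
translation), Gaussian keypoint noise (0.01 trunk lengths), i.i.d.
keypoint dropout (2%) and low-confidence assignment (3%) emulate recording
and detection imperfections. The default duration is 16 s: one full 15 s
clip per subject, so an 83 + 26 cohort yields an 83/26 clip table, the
cohort shape the classification stage is designed around.

The delay effect multiplies every oscillator's amplitude by 0.4 and
frequency by 0.6 (a hypokinesia proxy) and blends the left/right drives
with weight 0.5 (reduced movement independence). The *direction* of these
effects is a modeling choice, not a clinical claim. Base oscillators
(amplitudes 1.6–2.0 rad, frequencies 1.2–1.4 Hz effective after the 0.6×
multiplier for the delayed class) were chosen, via the analytic sinusoid
speed formula plus the rolling-mean filter's attenuation, so that
delay-attenuated motion still clears the 0.9 trunk-length/s activity gate
(typical clips score ≈ 2.5, delayed ≈ 1.25): the simulator emulates clips
that have already passed segment selection, as the modeling cohort it
stands in for did. Determinism is guaranteed by a fixed-algorithm
generator (NumPy PCG64) with per-subject spawned child seeds.

What the simulator does *not* model: 3-D motion and foreshortening,
anatomically coupled joint limits, fidgety/writhing movement character,
bursty occlusion (available as an option, off by default), pose-tracker
identity switches, or any validated biomechanics of infants. Passing tests
therefore show that the pipeline is correct and calibrated on data with a
known planted effect — not that the features or classifiers would reach
comparable accuracy on real infants.

## Calibration and effect recovery

Two end-to-end experiments anchor the statistics (recomputed by
`scripts/acceptance.py` and the test suite):

- **Null calibration.** Twenty zero-effect cohorts (83/26, effect
  multipliers 1, coupling 0) run through the full pipeline in leakage-safe
  mode. Because class imbalance survives into the held-out folds, the
  correct chance reference is not 0.5 but q·p + (1−q)(1−p), where p is the
  delayed prevalence and q the classifier's own predicted-delayed rate
  (pooled over folds); under the null, mean accuracy must sit within the
  95% binomial band of that level, and does.
- **Effect recovery.** A default-effect cohort (83/26, pinned seed) run in
  the default mode yields random-forest weighted F1 ≥ 0.9 (in practice
  ≈ 1.0), and the ANOVA stage retains the wrist/ankle speed features the
  generator actually perturbs — a qualitative, not numeric, echo of what
  the pipeline is designed to detect.

## Known limitations

- The 227-feature catalog is this package's normative reconstruction of a
  category-level description; other enumerations of the same categories are
  possible.
- The paper-faithful execution order leaks by construction; use
  `leakage_safe=True` for honest generalization estimates.
- 2-D kinematics conflate out-of-plane motion with speed changes; the
  trunk-length unit assumes the torso is roughly parallel to the image
  plane.
- Subject-level cross-validation grouping is not implemented; with several
  clips per infant, fold splits are clip-level and can share subjects
  across folds.
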