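# Methods

## Scope and data model

`kinegait` analyses overground walking trials recorded by a single depth
camera with skeletal body tracking: per frame, a timestamp and 32 joint
positions in millimetres in the camera frame. The package convention is
x mediolateral (positive toward the subject's left), y vertical
(positive up), z distance from the camera; the subject walks toward the
sensor, so z decreases over a trial. Trackers that natively report a
y-down depth frame must be normalized to y-up on export. Per-joint
confidence scores are stored when present but never gate analysis.

Nine joints drive all metrics: PELVIS, HIP_L/R, ANKLE_L/R, SHOULDER_L/R,
WRIST_L/R. The remaining 23 are carried for completeness and QA.

## Preprocessing

Consumer depth cameras deliver ~30 fps with noticeable timestamp jitter.
Each joint coordinate is therefore interpolated onto a uniform 50 Hz
grid with a **not-a-knot cubic spline** — chosen because it reproduces
cubic polynomials exactly and invents no boundary derivatives, so smooth
limb kinematics pass through unchanged (verified to 1e-6 mm on cubics in
the tests). Upsampling (rather than decimating to a common low rate)
preserves the temporal detail needed for event timing. The grid spans
`floor(duration × 50) + 1` samples from the first raw timestamp, never
extrapolating.

Noise is then removed with a **zero-phase 4th-order Butterworth low-pass
at 8 Hz** (forward–backward application, so the effective magnitude
response is the squared Butterworth gain and the phase lag is zero —
temporal event estimates are unbiased). 8 Hz keeps all voluntary gait
motion, including fast arm swing, while suppressing tracker jitter.
Filter order, cutoff and resampling rate are configuration with these
defaults, and are recorded in every output row.

All metrics are computed inside the **gait analysis path (GAP)**: the
slice where the pelvis camera distance lies within `[gap_near, gap_far]`
(defaults 1.5 m and 3.5 m — a 2 m corridor inside the range where depth
body tracking is dependable). Filtering precedes windowing so edge
transients fall outside the analysed slice. Entry and exit times are
linearly interpolated at the boundary crossings; their difference is the
traversal time behind gait velocity and cadence. A trial that ends with
the subject still inside the GAP yields a truncated-window warning.

## Gait events and spatiotemporal parameters

Events come from the z-component of the ankles only, expressed relative
to the pelvis to remove forward drift: `f(t) = pelvis_z − ankle_z` is
largest when the ankle is furthest ahead of the body. **Heel strike** is
a local maximum of `f`, **toe-off** a local minimum, accepted with
prominence ≥ 10 mm and separation ≥ 0.3 s (both configurable). This
pelvis-relative extremum rule is the standard choice for walkway (non-
treadmill) recordings. Heel strikes of the two sides must alternate;
violations are reported as warnings with the offending times.

Per side, averaged over that side's events inside the window: step
length (|ankle z separation| at heel strike), step width (|ankle x
separation|), step time (from the preceding contralateral strike), step
velocity (per-event length/time), stride length (z advance between
consecutive same-side strikes), double support (contralateral toe-off
minus strike), stance duration ((toe-off − strike)/stride time × 100).
Overall: gait velocity = GAP length / traversal time; cadence =
60 × step count / traversal time; step and stride counts. A side with
fewer than two strikes reports NaN stride metrics and is flagged.

Cadence deliberately uses the window step count rather than inverting
the mean step time: it is defined as a whole-gait parameter, and on
short windows the two estimators disagree because the count is an
integer — cadence is therefore strongly quantized on a 2 m corridor and
is excluded from tight recovery tests.

## Centre-of-mass sway

COM_HIP is the midpoint of the two hip joints. The subject's reference
path is a per-trial least-squares line of x (and of y) against forward
progress z; ML_SWAY and V_SWAY are the maximum absolute residuals in
millimetres. Fitting the line (rather than assuming the camera axis)
makes both parameters invariant to walking at a small constant angle to
the sensor. Note a property of this max-residual-after-detrend
definition: over a window containing only a few sway cycles, the fitted
line absorbs part of the oscillation and the attained maximum residual
differs from the raw sway amplitude by up to ~15% — the simulator's
ground truth therefore reports the metric's value on clean kinematics,
not the raw amplitude. Vertical motion is detrended the same way only;
the intrinsic double-bump vertical oscillation of gait is part of
V_SWAY, not removed.

## Arm swing

Linear metrics use the wrist displacement relative to the pelvis:
AP = pelvis_z − wrist_z (positive anterior), ML = wrist_x − pelvis_x,
UD = wrist_y − pelvis_y. Per direction: anterior maximum, posterior
minimum (≤ 0 by construction), peak-to-peak range. PATH_TOT is the
summed 3D chord length of the relative trajectory inside the GAP;
SWAY_AREA the area of the 2D convex hull of the (AP, ML) points
(zero with a warning when collinear); SPEED_AP the maximum
|central-difference derivative| of the AP component on the 50 Hz grid.

Angular metrics are the signed angle between the arm segment
(shoulder→wrist) and the same-side trunk segment (shoulder→hip), both
projected onto the sagittal (z, y) plane, positive when the arm is
anterior of the trunk line. The sagittal projection is what makes a
signed anterior/posterior decomposition possible; a full 3D angle is
unsigned. Samples with a projected segment under 10 mm are excluded
(warning above 5% exclusions).

**Asymmetry.** `asa(p_left, p_right) = |(45° − arctan(P_MORE/P_LESS))/90°| × 100`
with P_MORE/P_LESS the larger/smaller value. The index is symmetric,
scale-invariant, bounded in [0, 50], returns exactly 50 when one side is
zero, and is undefined when both are. It is reported for the angular
swing range (ASA_ANGLE), the total path (ASA_PATH) and the AP sway range
(ASA_AP_RANGE). ASA_ANGLE is computed from the **range**, not the
anterior maximum: the peak-to-peak amplitude is the quantity whose
asymmetry the index is meant to track, and it is the choice consistent
with the published worked examples the tests reproduce.

**Synchrony.** SI_ARMS is the Pearson correlation of the two wrists'
pelvis-relative AP series (healthy anti-phase swing gives values near
−1). SI_ARM_LEG correlates each arm segment's z-extension
(wrist_z − shoulder_z) with the opposite leg segment's z-extension
(ankle_z − hip_z), a sign convention under which in-phase forward motion
of opposite limbs is positive. The segment-extension reading (rather
than distal-joint displacement) was adopted where the definition was
open; both move together for the tested kinematics.

## The simulator and its ground truth

The simulator emulates the acquisition protocol: a subject walking at
`step_length / step_time` from `start_z` (default 5.5 m) toward the
camera along a 10 m walkway, sampled at a jittery 30 fps with isotropic
Gaussian positional noise (default 2 mm) added after all kinematics, so
ground truth stays closed-form. Defaults describe an unremarkable adult
walker: 0.60 m steps at 0.55 s, stance fraction 0.62, 25° arm
amplitude per side, 45/35 mm lateral/vertical COM sway.

Ankles alternate stance (planted) and swing (forward transport by one
stride) with a cosine-ramped plateau velocity profile (ramps over the
first/last 10% of swing). Zero endpoint velocity makes the
pelvis-relative AP extrema well defined; the exact clearance shape is
arbitrary and irrelevant to the tested metrics. Wrists swing as sagittal
pendulums (length 600 mm) with per-side angular amplitude, anti-phase
between arms, each peaking anterior at the contralateral heel strike; a
small quarter-phase ML wander (15 mm) keeps the (AP, ML) orbit
non-degenerate. All other joints ride rigidly on their parents.

`GroundTruth` reports, per parameter, the value the metric definition
attains on the noise-free kinematics. Two conventions matter:

* **Event times** follow the AP-extremum rule: the relative forward
  position of the swinging ankle peaks where the ankle's speed falls
  through the pelvis speed, a closed-form lag of
  `(2a/π)·asin(W·sw)·swing_duration` before touchdown (ramp fraction
  `a = 0.1`, profile normalization `W = 1 − 2a + 4a/π`, swing fraction
  `sw`). Stance duration and double support truths carry this lag;
  lengths, times and velocities use the nominal configured values.
* **Sway truths** are the max residuals the least-squares detrend
  attains on the clean COM path over the nominal window (see above).

The default two-group study design (`study_cohort_configs`) draws 16
impaired-like subjects (slower, shorter steps, longer stance, reduced
and asymmetric arm swing, larger lateral sway) and 13 control-like
subjects, two trials each — 58 trials, matching the sample accounting
the reporting layer replicates (side-wise parameters contribute two
observations per trial: 64 vs 52).

What the simulator does **not** model — and what passing recovery tests
therefore do not show about real recordings: body-tracking artefacts
(joint swaps, depth-dependent bias, occlusion dropouts), tremor,
freezing, turning, variable pace, soft-tissue and clothing effects, and
inter-stride variability beyond the configured noise. Recovery results
bound algorithmic error, not sensor error.

## Statistics

The reporting layer is a thin, reproducible wrapper over standard tests:
Shapiro–Wilk normality per group, Mann–Whitney for two-group differences
(rank-sum statistic W reported; U = W − n₁(n₁+1)/2; SciPy's
exact-or-asymptotic p policy), Student's t alongside, significance stars
at 0.05/0.01/0.001, and Spearman (optionally Pearson) correlation
matrices between arm-swing and spatiotemporal/COM parameters with
per-cell significance tiers. No multiple-testing correction is applied
by default (raw per-parameter p-values, as is common in this
literature). Pooling left/right observations as independent samples
ignores their within-subject correlation; p-values for side-wise
parameters are correspondingly optimistic.

## Numerical choices and degenerate inputs

* Resampling needs ≥ 4 frames (cubic support); filtering needs > 15
  samples (zero-phase padding); sway needs ≥ 10 samples and ≥ 0.2 m of
  forward travel; synchrony needs ≥ 25 window samples.
* Peak acceptance: 10 mm prominence, 0.3 s separation — far below any
  genuine step signature (hundreds of mm) but above filtered noise.
* `asa` returns its supremum 50 exactly at a zero side rather than
  relying on `atan` overflow; both-zero input raises.
* Zero-variance synchrony series and all-identical group observations
  raise/skip with explicit notes rather than emitting NaN silently.
* Simulated trial seeds fix the full output bit-for-bit; cohort trial
  seeds derive deterministically from the subject seed.

## Problem sizes

Default tests and the acceptance checks run the full 58-trial cohort
(~130 frames per trial, ~4 s of walking each); the whole suite completes
in well under a minute on one core. The Monte-Carlo checks use 200–500
seeded replicates for the power and type-I-error oracles, sizes at which
the binomial uncertainty of the checked rates is well inside the
asserted bands.
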