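# kinegait

Markerless gait analysis from 32-joint skeletal trajectories.

`kinegait` turns depth-camera body-tracking recordings (Azure-Kinect-style
JSON, one 32-joint skeleton per frame) of a subject walking toward the
sensor into a quantitative gait profile covering three aspects of walking:

* **spatiotemporal parameters** — step/stride length, step width, step
  time and velocity, stance and double-support duration, gait velocity,
  cadence, step counts — from heel-strike/toe-off events detected on the
  pelvis-relative anteroposterior ankle trajectories;
* **centre-of-mass sway** — maximum mediolateral and vertical deviation of
  the hip-midpoint (COM_HIP) from the fitted straight walking line;
* **arm swing** — wrist displacement relative to the pelvis (per-direction
  anterior/posterior extrema and ranges, total 3D path, convex-hull area,
  peak AP speed), sagittal shoulder–arm angles, the **absolute symmetry
  angle** asymmetry index

  ASA = |(45° − arctan(P_MORE / P_LESS)) / 90°| × 100 (%),

  where P_MORE/P_LESS are the larger/smaller of a left/right parameter
  pair (0 = perfect symmetry, 50 = fully one-sided), and **synchrony
  indices**: the Pearson correlation between the two arms' AP series
  (SI_ARMS, strongly negative in healthy anti-phase swing) and between
  each arm and the opposite leg (SI_ARM_LEG, positive).

It is written for movement scientists and rehabilitation researchers who
want digital gait biomarkers — e.g. the reduced, asymmetric arm swing that
accompanies Parkinsonian gait — without marker-based motion capture.

All metrics are computed inside a configurable *gait analysis path* (GAP):
the corridor of camera distances (default 1.5–3.5 m) where depth tracking
is reliable. Raw jittery ~30 fps frames are cubic-spline resampled to a
uniform 50 Hz grid and low-pass filtered (zero-phase 4th-order
Butterworth, 8 Hz) before any metric is computed.

A parametric synthetic-walking simulator (`kinegait.synth_gait`)
generates full 32-joint trials with closed-form ground truth for every
parameter, so the entire pipeline is validated by parameter recovery
without any recorded data.

## Worked example

```python
from kinegait import SynthConfig, generate, analyze_trial, asa

cfg = SynthConfig(arm_amplitude_deg=(28.0, 14.0), seed=42)  # right arm halved
trial, truth = generate(cfg)
row = analyze_trial(trial)

print(f"gait velocity   {row['GAIT_VEL']:.2f} m/s")
print(f"angle range L/R {row['ANGLE_RANGE_L']:.1f}/{row['ANGLE_RANGE_R']:.1f} deg")
print(f"ASA_ANGLE       {row['ASA_ANGLE']:.2f} %")
print(f"SI_ARMS         {row['SI_ARMS']:.3f}")
```

prints

```
gait velocity   1.09 m/s
angle range L/R 55.5/28.1 deg
ASA_ANGLE       20.15 %
SI_ARMS         -0.999
```

The subject walks at the configured 1.09 m/s; the sagittal arm-swing
ranges recover the configured 56°/28° amplitudes; their asymmetry index
(20.15%) matches the closed form `asa(28, 14) = 20.48` within the noise
of a single trial; and the arms are almost perfectly anti-phase
(SI_ARMS ≈ −1), as in healthy coordination.

## Command line

```sh
kinegait validate trial.json              # schema + invariant check
kinegait simulate --config cohort.yaml --out trials/ --trials 2
kinegait analyze trials/ -o rows.csv      # one parameter row per trial
kinegait compare impaired.csv control.csv -o report/
```

`compare` writes the classic two-group table — per-parameter median
(Q1, Q3) per group, Mann–Whitney rank-sum statistic and p-value with the
Student's t-test alongside, significance stars — plus Spearman
correlation matrices between arm-swing and spatiotemporal/COM parameters.

## Documentation

`docs/methods.md` describes the kinematic model, the metric definitions,
the simulator's ground-truth conventions, numerical choices and known
limitations.
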