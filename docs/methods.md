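# Methods

## Model and assumptions

The tracker assumes an appearance model in which the on-screen gaze point is
an affine function of the pupil-center position in the camera image, valid
locally around a reference point, and a head model in which yaw/pitch
rotations re-aim the head at a screen coordinate computed by a tangent
projection from the viewing distance.  Head motion is handled by moving the
*origin* of the affine map (the reference point, via head-pointing) and its
pupil anchor (via eye-corner displacement), rather than by re-fitting the
map.  The assumptions that matter:

- **Local linearity.** The pupil's image displacement is proportional to
  the sine of the eye's rotation, while screen position grows with the
  tangent; the edge-dot calibration fits the chord between the screen
  edges.  Over the ±25° (horizontal) span of a 48 cm screen at 50 cm this
  sine-vs-tangent mismatch is the dominant systematic error: ~0.1 × offset
  at mid-range eccentricities, vanishing at the center and at the
  calibration dots.  On the noiseless rig it amounts to a mean error of
  0.92° over the 4×4 grid — the floor of the method, independent of
  landmark quality.
- **Corners displace like the pupil.** The benchmark update (step 3)
  replaces the unobservable "pupil when fixating the new reference point"
  with the mean inner/outer eye-corner displacement.  For rigid motion this
  is exact only when the corner points sit at the same depth as the pupil:
  a depth offset Δz produces a benchmark bias of Δz·sin(yaw) millimetres,
  which the ~45× screen-to-pupil amplification turns into degrees per few
  millimetres of Δz.  The package's face model therefore places its corner
  points in the corneal plane (z = 3 mm behind the nose tip) — the geometry
  under which the method's own approximation holds; the sensitivity to Δz
  is a real limitation of the corner-update idea and is exposed by moving
  the rig's corner points rearward.
- **Fixed viewing distance.** `d` is a per-session constant; translations
  toward/away from the screen are not modelled or compensated.
- **Pitch sign.** The head-pointing vertical term is implemented as printed
  (`dy = d(tanβ + tanβ₀)`, `pitch_mode="printed"`), which cancels only when
  the calibration pitch is the negative of the current pitch; the
  conventional difference form is available as `pitch_mode="difference"`.
  With a neutral calibration pose (β₀ = 0, the rig's default) the two are
  identical.

## Parameters

| parameter | default | meaning |
|---|---|---|
| viewing distance `d` | 500 mm | user-to-screen distance |
| screen | 1920×1080 px, 480×270 mm | 0.25 mm/px pitch |
| head-state dead-band | 2° | yaw/pitch deviation (strict >) that declares motion |
| stop detection | <0.5°/frame for 3 frames | ends a motion episode; at 30 Hz this is a 15°/s velocity floor — slower head drift is treated as stillness |
| calibration dwell / window | 2 s / 0.5 s | per-dot fixation and averaging window |
| calibration stability | 2° | max pose deviation across the five dots (reuses the dead-band value) |
| edge-dot margin | 30 px | distance of the four edge dots from the screen edges |
| scale sanity range | 5–500 | plausible magnitude of the scale coefficients |
| I-VT velocity threshold | 30°/s | saccade/fixation boundary (no printed reference value exists; this is the conventional choice) |
| I-VT minimum fixation | 60 ms | shorter fixation runs are discarded; gap rule breaks runs at >3 nominal frame intervals |
| heatmap sigma | 2% of screen width | Gaussian kernel, truncated at 3σ, normalised to unit mass |

The pupil center is the designated iris-center landmark (indices 468/473),
not the centroid of the 4-point iris ring; `left`/`right` are image-space
labels.

## The synthetic rig

The rig emulates the assumed geometry directly: a rigid head (six-point
face model plus inner corners and two eyeballs of 12 mm radius, no kappa
angle between visual and optical axis) at 500 mm from a 1920×1080 screen,
observed by a distortion-free pinhole camera (f = 800 px, 1280×960) at the
screen's top-center with axes aligned to the screen.  Head rotations pivot
about a neck point 80 mm below/behind the face origin, so rotation also
translates the eyes and genuinely exercises the corner-displacement update.
Eyes fixate the commanded target exactly and instantaneously.  Head
reorientations toward a new dot ramp over 0.3 s with a smoothstep profile,
matching natural head-saccade velocities (a 5–12° turn peaks at 25–60°/s,
above the tracker's 15°/s detection floor).  Landmark jitter, when enabled,
is i.i.d. isotropic Gaussian per landmark per frame from a single seeded
generator.

What the rig does **not** emulate — and hence what green tests do not show
about real data: landmark-detector noise structure (temporally correlated,
heteroscedastic, blink dropouts), smooth-pursuit latency and gain < 1,
torsional eye movement, eyelid occlusion, depth translations, and
anatomical corner placement (see the Δz sensitivity above).  Conversely the
rig's spherical-eye kinematics expose the sine-vs-tangent floor that real
noise partially masks.

## Numerical choices

- PnP is solved by Levenberg–Marquardt on a rotation-vector + translation
  parameterisation with an analytic pinhole/distortion forward model;
  the depth is initialised from the metric-to-pixel spread ratio, and the
  tracker warm-starts each frame from the previous solution.  Collinear
  image points are detected by the singular-value ratio and yield an
  invalid pose rather than a solve.
- Checkerboard intrinsics use the planar-homography closed form (normalised
  DLT per view, absolute-conic constraints) followed by full-bundle LM
  refinement of intrinsics, five distortion coefficients and per-view
  extrinsics.  A second near-zero singular value of the constraint matrix
  (e.g. duplicated views) is rejected as ill-conditioned.
- Dead-band and stability comparisons use strict inequality at the
  threshold (a deviation of exactly 2° counts as still).
- Gaze points and head-pointing outside the screen are clamped to
  `[0, res−1]` and flagged rather than dropped.
- All CSV artifacts write floats with `repr`, so logs round-trip
  bit-exactly and repeated seeded runs are byte-identical.
- Angles are averaged arithmetically during calibration (they are small and
  far from wrap-around).

## Design choices that were genuinely open

- **Motion-end rule**: inter-frame pose change below 0.5° for 3 consecutive
  frames; during motion the head-pointing and pupil benchmarks are
  recomputed every frame so gaze output never pauses.
- **Dead-band reference**: head state is judged against the pose associated
  with the current reference point (not the previous frame), making the 2°
  threshold a position dead-band rather than a velocity gate.
- **Benchmark pose (θ₀, β₀)** is never updated after calibration; only the
  reference point and pupil benchmarks move.
- **Corner displacements** are signed 2D vectors, averaged componentwise.
- **No temporal smoothing** of gaze output by default; an optional
  moving-average window exists but is off.

## Evaluation sizes

The packaged evaluation uses the full study conditions: 30 Hz sampling,
16 dots × 3 s, 5-dot calibration × 2 s, pursuit laps of 30 s (rectangle,
1200×600 px at 120 px/s) and 24 s (circle, 350 px radius at 15°/s); unit
tests reuse the same geometry at 10 Hz.  On the noiseless rig the method
lands at 0.92° mean error with the head fixed, 1.48° with the head turning
toward targets, and 15.8° with the benchmark update ablated; pursuit errors
(0.83° rectangle, 0.60° circle) fall *below* the fixation error because the
rig's eyes track without pursuit lag and the trajectories lie in
lower-systematic-error screen regions.

## Known limitations

- The corner-based benchmark update is first-order exact only for the
  stylised corner placement discussed above; with anatomically deeper
  corners its bias grows linearly in depth offset and rotation angle.
- The printed "+" pitch form double-counts a non-zero calibration pitch;
  sessions calibrated with a tilted head should use
  `pitch_mode="difference"`.
- The tracker assumes the camera's axes are aligned with the screen; a
  tilted webcam folds its tilt into the pose benchmark and, under the
  printed pitch form, into the vertical head-pointing.
- No blink/occlusion handling beyond invalid-sample propagation; no
  multi-face support; live landmark detection is out of core scope (any
  backend satisfying the frame protocol can be plugged in).
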