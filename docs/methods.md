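# Methods

## Problem and pipeline

`cervimotion` assesses cervical-spine mobility from video-derived face-mesh
landmarks. A recording of a guided exercise session — flexion/extension,
left/right axial rotation, left/right lateral bending, three repetitions
each — is reduced to per-frame head-pose angles, differentiated into
angular velocities, segmented into per-repetition extremes, and scored
against standard values. A mosaic anonymizer removes facial identity from
feedback video frames.

The pipeline operates on 468-point face-mesh landmark sequences (the
format produced by common real-time face-mesh detectors) with normalized
image coordinates: x rightward and y downward in [0, 1], z in detector
landmark units, more negative toward the camera. Detector inference
itself is out of scope; an adapter can feed live detections into the same
schema.

## Head-pose model

Six landmarks carry the pose signal: the nose bridge (indices 2 bottom,
6 top) and the four eye corners (33/133 left, 263/362 right), each eye
summarized by its corner midpoint. Three slopes give the three degrees of
freedom:

    kx = (z_top_nose − z_bottom_nose) / (y_top_nose − y_bottom_nose)   pitch = arctan kx
    ky = (z_right_eye − z_left_eye)  / (x_right_eye − x_left_eye)      yaw   = arctan ky
    kz = (y_right_eye − y_left_eye)  / (x_right_eye − x_left_eye)      roll  = arctan kz

reported in degrees. This is deliberately not a full Euler decomposition
of a 6-DOF pose: each angle is read from a segment whose orientation is
insensitive to the other two rotations at rest symmetry, which makes
single-axis excursions exact under orthographic viewing but leaves
combined-axis coupling unmodeled. Cervical exercises are performed one
axis at a time, so this is the regime that matters.

Assumptions and their consequences:

- **Unit mixing.** x, y are normalized by image size while z is in
  detector units; the slopes therefore recover exact angles only when all
  three share a scale (as in the synthetic generator). Against a metric
  rig the absolute angles would carry a fixed unit-ratio distortion;
  scoring is ratio-based per direction, which cancels a common scale.
- **Sign convention** (fixed, since scoring uses per-side magnitudes any
  consistent choice works): positive pitch = extension (head up),
  positive yaw = rotation toward the subject's left, positive roll = tilt
  toward the left shoulder.
- **Degenerate denominators**: |den| < 1e−9 flags the slope undefined;
  the angle saturates to ±90° by numerator sign, or is invalid if the
  numerator also vanishes. At 90° yaw the eye abscissas coincide; this is
  far outside the cervical range and only matters for robustness.

## Series processing

Angles are computed per frame; no-face frames are first-class so the time
base stays uniform. Interior gaps of at most `max_gap` frames (default
15, i.e. 0.5 s at 30 fps) are linearly interpolated; longer gaps stay
invalid. A centered moving average (default window 5 frames, window 1 =
off) suppresses landmark jitter before differentiation; the window
shrinks symmetrically at valid-span edges so constants are preserved and
no invalid sample leaks in. Velocity uses the second-order central
difference on interior frames and one-sided differences at span ends.
A 5-frame average attenuates a half-sine peak of duration T by a factor
1 − (π/(T·fps))² at 30 fps — under 0.2% at the default exercise tempo,
well inside the 0.5° recovery tolerance used throughout.

## Repetition extremes

For each of the six direction-sides the signed angle series (negated for
the negative side) is searched for local maxima with prominence ≥ 5° and
separation ≥ 1 s (both configurable; the defaults match a 3-repetition
protocol at a comfortable tempo with rests). The three largest peaks are
the amplitude extremes; within each peak's excursion — bounded by the
surrounding zero-crossings or valid-span ends — the largest |ω| is the
paired velocity extreme. Sides with fewer than three detected excursions
report missing entries, which score zero and are flagged distinctly from
measured zeros. The six sides are detected independently, so any exercise
order is accepted. Stored extremes are sorted descending per side; the
scoring sum is permutation-invariant within a side, so this does not
change totals.

## Scoring

36 score points: per direction-side (k ∈ {x, y, z}, side j ∈ {1, 2}) and
repetition i ∈ {1, 2, 3}, an amplitude term and a velocity term

    min(α0_kj, α_kji)/α0_kj · a_kj  +  min(ω0_kj, ω_kji)/ω0_kj · b_kj .

Default weights (points): a = (x1 2.25, x2 2.82, y1 2.90, y2 2.82,
z1 2.90, z2 2.82), b = (x1 3.06, x2 3.09, y1 2.75, y2 2.58, z1 2.75,
z2 2.58); the attainable total is 3 × (16.51 + 16.81) = 99.96, i.e. a
nominal 100 up to the two-decimal weight rounding.

Standards: normative amplitude ranges per axis and sex (male 68° pitch,
145° yaw, 45° roll; female 76°, 139°, 45°). Flexion+extension and total
rotation are conventionally quoted as two-side sums and lateral bending
per side, so pitch and yaw totals are split equally across sides and roll
is used per side — a configurable default, overridable by explicit
per-side values in the profile. Velocity standards have no normative
table; they must come from a standard-movement recording (the
`reference_standard_profile` path, which runs the full measurement
pipeline on a noiseless standard plan), so a profile without `omega0` is
rejected.

Reduced scoring standards for ablation: amplitude-only, velocity-only,
and per-axis/axis-pair restrictions of the full sum. Amplitude-only plus
velocity-only equals the full variant identically.

## Repeatability and agreement metrics

Repeatability: per-frame sample standard deviation (divisor n − 1) of the
angle across n ≥ 2 runs of the same recording, summarized by its mean
over frames. The pipeline is deterministic, so repeated runs on identical
input give exactly 0; nonzero values arise only from nondeterministic
upstream detectors or genuinely different inputs.

Agreement between benchmark and predicted scores: RMSE, MAE, R² (about
the benchmark mean, possibly negative), Kendall's tau-a (no tie
correction; ties count as neither concordant nor discordant), and
extrapolated rank-biased overlap. RBO's persistence defaults to 0.9 and
ties in scores are broken by subject identifier for reproducibility —
explicit package choices, as no single convention is universal.

## Mosaic anonymizer

The face box is tiled into `mosaic_size`-pixel squares anchored at the
box's top-left; each pixel takes the original color of its square's
top-left pixel. Anchors are read from an unmodified copy, making the
operation order-independent and idempotent; edge-overhanging squares
still anchor at their own top-left; pixels outside the box are untouched.
The guarantee is information loss (non-injectivity), not cryptographic
security. Frame I/O uses PNG sequences, which keeps pixel-exact testing
possible; container video support would sit behind the same per-frame
function.

## Synthetic motion generator

The generator defines the study conditions for every test. A canonical
head-centered 3-D face template (inter-ocular distance 0.30 template
units, nose-bridge length 0.20 — the 1.5 ratio of plausible facial
proportions; the 462 non-key points on a deterministic ellipsoid lattice)
is rotated by R = Rz(roll)·Ry(yaw)·Rx(pitch) and projected
orthographically to the normalized landmark frame, with optional
isotropic Gaussian coordinate noise (seeded).

Each planned repetition is a half-sine excursion θ(t) = A sin(πt/T) whose
duration follows from the planned peak velocity (T = πA/ω). The standard
plan performs three repetitions per direction-side at the per-side
normative amplitudes, paced at 2.5 s per repetition — implied peak
velocities of roughly 40–90°/s, a comfortable guided-exercise tempo;
repetitions and phases are separated by 1 s rests.

What the generator does *not* emulate: perspective distortion, detector
noise structure (landmark noise is isotropic i.i.d. Gaussian, real
detectors err anisotropically and with temporal correlation), torso
compensation, occlusion, and combined-axis motion. Passing tests
therefore demonstrate algorithmic correctness of the pipeline under its
own geometric model, not field accuracy against a motion-capture rig.

## Numerical choices

- Denominator epsilon 1e−9 (normalized units); angle saturation at ±90°.
- Landmark files store 6 decimals; round-trip identity is defined at that
  precision. File-mediated pipelines can sit ~0.1 point below in-memory
  totals at the full score because quantized extremes fall marginally
  short of their standards.
- Frame quantization bounds amplitude recovery error by A(1 − cos(π/(T·fps))),
  ≈ 0.005° at default tempo — the basis of the 0.5° test tolerances.
- Peak detection: scipy `find_peaks`; a peak needs interior samples, so
  excursions truncated exactly at the series boundary are not counted.
- Ties in ranking construction broken by identifier; all randomness goes
  through seeded `numpy` generators.

## Problem sizes used in validation

The standard plan renders ≈ 64 s at 30 fps (≈ 1920 frames × 468
landmarks); end-to-end checks run four such pipelines (fractions 0.25,
0.5, 1.0, 1.25 of standard effort) in a few seconds. Metric oracles use
brute-force pair counting for n ≤ 10 and depth-wise RBO summation at
n ≤ 12 — sizes where exhaustive enumeration is exact and fast.

## Known limitations

- Absolute angle accuracy with mixed-unit real detector output is
  untested (no metric ground truth available to the package).
- Combined-axis motion is not decomposed; simultaneous rotations bleed
  between axes.
- The velocity standard depends entirely on the chosen standard
  recording; two clinics with different standard subjects will produce
  incomparable velocity subscores.
- Amplitude extremes assume excursions return near zero between
  repetitions; a subject holding a sustained deflection merges
  repetitions into one excursion.
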