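# cervimotion

Video-based assessment of cervical-spine mobility for rehabilitation
monitoring. Given a per-frame 468-point face-mesh landmark sequence of a
patient performing a guided neck exercise (flexion/extension, left/right
axial rotation, left/right lateral bending, three repetitions each),
`cervimotion` computes 3-DOF head-pose angles, angular-velocity series,
per-repetition range-of-motion and speed extremes, and a weighted
0–100 score of cervical mobility. It also provides a mosaic face
anonymizer for feedback video, repeatability and rank-agreement metrics
for validating scoring standards, and a synthetic exercise-motion
generator with exact ground truth.

Audience: engineers and clinical researchers building unmanned
rehabilitation-exercise monitoring from a single camera, where facial
landmarks are available but raw video must not leave the device
unanonymized.

## Model

Six landmarks — nose bridge bottom/top (indices 2, 6) and the eye-corner
midpoints (33+133, 263+362) — give three slopes, whose arctangents are
the head-pose angles in degrees:

    pitch = arctan[(z_tn − z_bn)/(y_tn − y_bn)]
    yaw   = arctan[(z_re − z_le)/(x_re − x_le)]
    roll  = arctan[(y_re − y_le)/(x_re − x_le)]

Angular velocity is the central difference of the smoothed angle series.
Per direction-side (axis k ∈ {x, y, z} × side j ∈ {1, 2}), the three
largest excursion peaks α_kj1..3 and their within-excursion peak speeds
ω_kj1..3 are scored against standards α⁰_kj, ω⁰_kj with weights a_kj,
b_kj:

    score = Σ_k Σ_j Σ_i [ min(α⁰,α_i)/α⁰ · a_kj + min(ω⁰,ω_i)/ω⁰ · b_kj ]

Each of the 36 score points saturates at its weight; the default weights
sum to an attainable total of 99.96 points (nominally 100). Amplitude
standards default to normative per-axis ranges by sex; velocity standards
are measured from a standard-movement recording. See `docs/methods.md`
for assumptions, parameter defaults, and limitations.

## Worked example

Score a synthetic subject who performs the exercise at 80% of the
standard amplitudes and speeds:

```python
from cervimotion import synthmotion as sm, landmarks as lm
from cervimotion.landmarks import Sex

standard = sm.standard_plan(Sex.MALE)          # normative amplitudes, 2.5 s reps
subject = sm.scaled_plan(standard, 0.8)        # 80% effort
lm.write_landmark_sequence(sm.generate_sequence(subject, sex=Sex.MALE), "subject.csv")
sm.reference_standard_profile(standard, Sex.MALE).to_json("standards.json")
```

```
$ cervimotion score --landmarks subject.csv --standards standards.json \
      --sex male --out report.json
total score: 79.97 / 99.96
```

`report.json` holds the full breakdown: every ratio is 0.8 and every
score point awards 80% of its weight, so the amplitude subtotal is 39.62
of 49.53, the velocity subtotal 40.34 of 50.43, and per-side subtotals
range 12.74 (flexion, x1) to 14.18 (extension, x2) — the total 79.97 is
0.8 × 99.96 up to frame quantization. A repetition the detector misses
would appear as a `"missing": true` score point awarding 0.

Other commands: `cervimotion synth` renders a plan JSON to a landmark
CSV, `cervimotion repeat` computes per-frame repeatability standard
deviations across repeated runs, and `cervimotion anonymize` mosaics
face boxes in a PNG frame sequence (`--grain` sets the square size).

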