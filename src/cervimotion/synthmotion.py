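"""Synthetic cervical-exercise head motion with known ground truth.

A canonical 3-D face template is rotated through planned exercise
trajectories and projected orthographically into the normalized landmark
coordinate frame, producing landmark sequences whose true per-repetition
amplitudes and peak angular velocities are known exactly.  This lets the
whole pipeline — angle recovery, extreme extraction, scoring — be
exercised end to end without any recorded video.

Model
-----
Each repetition is a half-sine excursion ``theta(t) = A sin(pi t / T)``
on a single axis, so the planned peak angular velocity ``pi A / T`` fixes
the repetition duration.  The head rotation applied to the template is
``R = Rz(roll) @ Ry(yaw) @ Rx(pitch)`` with the same sign convention the
angle estimator uses; under orthographic projection single-axis
excursions are recovered exactly (up to frame quantization), which
isolates algorithmic error from perspective and detector error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np

from . import headpose, kinematics
from .landmarks import (
    KEY_INDICES,
    N_LANDMARKS,
    LandmarkFrame,
    LandmarkSequence,
    Sex,
)
from .scoring import NORMATIVE_ROM_DEG, ScoreStandards

__all__ = [
    "FaceTemplate",
    "canonical_template",
    "Phase",
    "ExercisePlan",
    "standard_plan",
    "scaled_plan",
    "GroundTruth",
    "generate_angle_trajectory",
    "render_landmarks",
    "generate_sequence",
    "reference_standard_profile",
]


@dataclass(frozen=True)
class FaceTemplate:
    """Head-centered 3-D landmark template (template units, y down, z
    negative toward the camera).

    At rest the template is bilaterally symmetric: the four eye corners
    share one y and one z, and the two nose-bridge points share x and z,
    so all three orientation slopes vanish.
    """

    points: np.ndarray  # (468, 3)

    def __post_init__(self) -> None:
        if self.points.shape != (N_LANDMARKS, 3):
            raise ValueError(f"template must have shape ({N_LANDMARKS}, 3)")
        p = self.points
        eyes = p[[33, 133, 263, 362]]
        if not (np.allclose(eyes[:, 1], eyes[0, 1]) and np.allclose(eyes[:, 2], eyes[0, 2])):
            raise ValueError("eye corners must share y and z at rest")
        nose = p[[2, 6]]
        if not (np.allclose(nose[:, 0], nose[0, 0]) and np.allclose(nose[:, 2], nose[0, 2])):
            raise ValueError("nose points must share x and z at rest")

    @property
    def key_points(self) -> np.ndarray:
        return self.points[list(KEY_INDICES)]

    @property
    def interocular(self) -> float:
        left = 0.5 * (self.points[33] + self.points[133])
        right = 0.5 * (self.points[263] + self.points[362])
        return float(np.linalg.norm(right - left))


def canonical_template() -> FaceTemplate:
    """The default face template with plausible facial proportions.

    Inter-ocular distance 0.30 template units, nose-bridge length 0.20
    (ratio 1.5); the remaining mesh points are laid out deterministically
    on a head-sized ellipsoid (their exact placement is irrelevant to the
    angle formulas, which read only the six key landmarks).
    """
    pts = np.zeros((N_LANDMARKS, 3))
    # Deterministic filler: Fibonacci lattice on an ellipsoid.
    idx = np.arange(N_LANDMARKS, dtype=float)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * idx / golden
    zlat = 1 - 2 * (idx + 0.5) / N_LANDMARKS
    r = np.sqrt(np.maximum(0.0, 1 - zlat**2))
    pts[:, 0] = 0.25 * r * np.cos(theta)
    pts[:, 1] = 0.30 * zlat
    pts[:, 2] = -0.10 - 0.12 * r * np.abs(np.sin(theta))
    # Key landmarks overwrite their filler positions.
    pts[2] = (0.0, 0.18, -0.12)  # nose bottom
    pts[6] = (0.0, -0.02, -0.12)  # nose top
    pts[33] = (-0.21, -0.05, -0.05)  # left eye, outer corner
    pts[133] = (-0.09, -0.05, -0.05)  # left eye, inner corner
    pts[362] = (0.09, -0.05, -0.05)  # right eye, inner corner
    pts[263] = (0.21, -0.05, -0.05)  # right eye, outer corner
    return FaceTemplate(points=pts)


@dataclass(frozen=True)
class Phase:
    """Consecutive repetitions on one direction-side.

    Each repetition is defined by its peak amplitude (degrees) and peak
    angular velocity (deg/s); the half-sine duration follows as
    ``pi * amplitude / peak_velocity``.
    """

    side: str
    amplitudes_deg: tuple[float, ...]
    peak_velocities_dps: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.side not in kinematics.DIRECTION_SIDES:
            raise ValueError(f"unknown direction-side {self.side!r}")
        if len(self.amplitudes_deg) != len(self.peak_velocities_dps):
            raise ValueError("amplitudes and peak velocities must pair up")
        if len(self.amplitudes_deg) < 1:
            raise ValueError("phase needs at least one repetition")
        if any(a < 0 for a in self.amplitudes_deg):
            raise ValueError("amplitudes must be non-negative")
        if any(w <= 0 for w in self.peak_velocities_dps):
            raise ValueError("peak velocities must be positive")

    @property
    def durations_s(self) -> tuple[float, ...]:
        return tuple(
            np.pi * a / w for a, w in zip(self.amplitudes_deg, self.peak_velocities_dps)
        )


@dataclass(frozen=True)
class ExercisePlan:
    """An ordered exercise protocol plus rendering noise parameters.

    ``rest_s`` separates repetitions and phases (and pads the start and
    end); ``noise_sd`` is isotropic Gaussian landmark noise in template
    units, applied per coordinate after projection.
    """

    phases: tuple[Phase, ...]
    rest_s: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rest_s <= 0:
            raise ValueError("rest_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def sides(self) -> set[str]:
        return {ph.side for ph in self.phases}

    def to_json(self, path=None) -> str:
        payload = {
            "rest_s": self.rest_s,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "phases": [
                {
                    "side": ph.side,
                    "amplitudes_deg": list(ph.amplitudes_deg),
                    "peak_velocities_dps": list(ph.peak_velocities_dps),
                }
                for ph in self.phases
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ExercisePlan":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            phases=tuple(
                Phase(
                    side=ph["side"],
                    amplitudes_deg=tuple(ph["amplitudes_deg"]),
                    peak_velocities_dps=tuple(ph["peak_velocities_dps"]),
                )
                for ph in payload["phases"]
            ),
            rest_s=payload.get("rest_s", 1.0),
            noise_sd=payload.get("noise_sd", 0.0),
            seed=payload.get("seed", 0),
        )


def standard_plan(
    sex: Sex = Sex.MALE,
    rep_duration_s: float = 2.5,
    repetitions: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExercisePlan:
    """A plan exercising all six direction-sides at the normative limits.

    Every repetition reaches the per-side normative amplitude (flexion/
    extension and rotation totals split equally across sides; bending per
    side), paced at ``rep_duration_s`` per repetition — a comfortable
    exercise tempo whose implied peak velocities fall in the tens of
    deg/s, typical of guided cervical exercise.
    """
    rom = NORMATIVE_ROM_DEG[sex]
    per_side = {
        "x1": rom["pitch"] / 2, "x2": rom["pitch"] / 2,
        "y1": rom["yaw"] / 2, "y2": rom["yaw"] / 2,
        "z1": rom["roll"], "z2": rom["roll"],
    }
    phases = []
    for side in kinematics.DIRECTION_SIDES:
        amp = per_side[side]
        vel = np.pi * amp / rep_duration_s
        phases.append(
            Phase(
                side=side,
                amplitudes_deg=(amp,) * repetitions,
                peak_velocities_dps=(vel,) * repetitions,
            )
        )
    return ExercisePlan(phases=tuple(phases), noise_sd=noise_sd, seed=seed)


def scaled_plan(plan: ExercisePlan, fraction: float) -> ExercisePlan:
    """Scale every amplitude and peak velocity by ``fraction``.

    Repetition durations are unchanged (both scale together), emulating a
    subject who moves through a reduced range at proportionally reduced
    speed.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    return replace(
        plan,
        phases=tuple(
            Phase(
                side=ph.side,
                amplitudes_deg=tuple(fraction * a for a in ph.amplitudes_deg),
                peak_velocities_dps=tuple(fraction * w for w in ph.peak_velocities_dps),
            )
            for ph in plan.phases
        ),
    )


@dataclass
class GroundTruth:
    """Planned per-frame angles plus the exact per-repetition extremes."""

    fps: float
    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray
    #: side -> list of (amplitude_deg, peak_velocity_dps) per repetition
    extremes: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def axis(self, name: str) -> np.ndarray:
        return {"pitch": self.pitch, "yaw": self.yaw, "roll": self.roll}[name]

    def __len__(self) -> int:
        return len(self.pitch)


def generate_angle_trajectory(plan: ExercisePlan, fps: float = 30.0) -> GroundTruth:
    """Sample the plan's ground-truth angle trajectory at ``fps``."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    # Lay out repetitions on the time axis.
    events = []  # (t0, T, axis, signed_amplitude)
    extremes: dict[str, list[tuple[float, float]]] = {}
    cursor = plan.rest_s
    for ph in plan.phases:
        axis = kinematics.SIDE_AXIS[ph.side]
        sign = kinematics.SIDE_SIGN[ph.side]
        extremes.setdefault(ph.side, [])
        for amp, vel, dur in zip(ph.amplitudes_deg, ph.peak_velocities_dps, ph.durations_s):
            events.append((cursor, dur, axis, sign * amp))
            extremes[ph.side].append((amp, vel))
            cursor += dur + plan.rest_s

    n = int(np.ceil(cursor * fps)) + 1
    t = np.arange(n) / fps
    series = {"pitch": np.zeros(n), "yaw": np.zeros(n), "roll": np.zeros(n)}
    for t0, dur, axis, amp in events:
        mask = (t >= t0) & (t <= t0 + dur)
        series[axis][mask] += amp * np.sin(np.pi * (t[mask] - t0) / dur)
    return GroundTruth(fps=fps, extremes=extremes, **series)


def _rotation(pitch_deg: float, yaw_deg: float, roll_deg: float) -> np.ndarray:
    """R = Rz(roll) @ Ry(yaw) @ Rx(pitch), matching the estimator's signs."""
    th, ps, ph = np.radians([pitch_deg, yaw_deg, roll_deg])
    rx = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
    ry = np.array([[np.cos(ps), 0, -np.sin(ps)], [0, 1, 0], [np.sin(ps), 0, np.cos(ps)]])
    rz = np.array([[np.cos(ph), -np.sin(ph), 0], [np.sin(ph), np.cos(ph), 0], [0, 0, 1]])
    return rz @ ry @ rx


def render_landmarks(
    truth: GroundTruth,
    template: FaceTemplate | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sex: Sex = Sex.UNSPECIFIED,
) -> LandmarkSequence:
    """Render a ground-truth trajectory as a face-mesh landmark sequence.

    Template points are rotated per frame, projected orthographically into
    normalized image coordinates (image center 0.5, unit scale, so z stays
    in the same units as x and y), then perturbed by isotropic Gaussian
    noise of standard deviation ``noise_sd`` (template units) drawn from a
    generator seeded with ``seed``.
    """
    template = template or canonical_template()
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(len(truth)):
        rot = _rotation(truth.pitch[i], truth.yaw[i], truth.roll[i])
        proj = template.points @ rot.T
        proj[:, 0] += 0.5
        proj[:, 1] += 0.5
        if noise_sd > 0:
            proj = proj + rng.normal(0.0, noise_sd, proj.shape)
        frames.append(LandmarkFrame(i, i / truth.fps, proj))
    return LandmarkSequence(fps=truth.fps, frames=frames, subject_sex=sex)


def generate_sequence(plan: ExercisePlan, fps: float = 30.0, sex: Sex = Sex.UNSPECIFIED) -> LandmarkSequence:
    """Plan -> trajectory -> rendered landmark sequence, in one call."""
    truth = generate_angle_trajectory(plan, fps)
    return render_landmarks(truth, noise_sd=plan.noise_sd, seed=plan.seed, sex=sex)


def reference_standard_profile(
    plan: ExercisePlan,
    sex: Sex = Sex.UNSPECIFIED,
    fps: float = 30.0,
    smooth_window: int = 5,
) -> ScoreStandards:
    """Build scoring standards from a noiseless standard exercise rendering.

    Mirrors how standard velocity values are obtained in practice: run the
    full measurement pipeline on a recording of standard movements and
    take the extreme values as the standards.  The plan must cover all six
    direction-sides; the largest measured amplitude and angular speed of
    each side become its ``alpha0`` and ``omega0``.
    """
    missing = set(kinematics.DIRECTION_SIDES) - plan.sides()
    if missing:
        raise ValueError(f"plan does not cover direction-sides: {sorted(missing)}")
    clean = replace(plan, noise_sd=0.0)
    seq = generate_sequence(clean, fps=fps, sex=sex)
    a = headpose.angle_series(seq, smooth_window=smooth_window)
    v = headpose.angular_velocity(a)
    ext = kinematics.find_extremes(a, v)
    alpha0 = {}
    omega0 = {}
    for side in kinematics.DIRECTION_SIDES:
        amps = [x for x in ext.alpha[side] if x is not None]
        vels = [x for x in ext.omega[side] if x is not None]
        if not amps or not vels:
            raise ValueError(f"standard plan produced no measurable extremes on {side}")
        alpha0[side] = max(amps)
        omega0[side] = max(vels)
    return ScoreStandards(alpha0=alpha0, omega0=omega0, sex=sex)
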