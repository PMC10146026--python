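"""Head-pose Euler angles and angular velocity from face-mesh landmarks.

Three slopes summarize head orientation: the nose-bridge depth gradient
gives pitch, the inter-eye depth gradient gives yaw, and the in-plane
eye-line slope gives roll::

    kx = (z_top_nose - z_bottom_nose) / (y_top_nose - y_bottom_nose)
    ky = (z_right_eye - z_left_eye)  / (x_right_eye - x_left_eye)
    kz = (y_right_eye - y_left_eye)  / (x_right_eye - x_left_eye)

    pitch = arctan(kx),  yaw = arctan(ky),  roll = arctan(kz)

all reported in degrees.  Sign convention (with image x rightward, y
downward): positive pitch is extension (head up), positive yaw is axial
rotation toward the subject's left, positive roll is lateral bending
toward the subject's left shoulder.  Scoring downstream uses per-side
magnitudes, so any consistent convention is workable; this one is fixed
and matched by the synthetic-motion generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import KeyPoints, LandmarkFrame, LandmarkSequence, extract_key_points

__all__ = [
    "KRatios",
    "PoseAngles",
    "AngleSeries",
    "VelocitySeries",
    "k_ratios",
    "angles_from_frame",
    "angle_series",
    "angular_velocity",
    "write_angle_series_csv",
    "write_velocity_series_csv",
]

#: Denominator threshold (normalized image units) below which a slope is
#: undefined and the corresponding angle saturates at +/-90 deg.
DENOM_EPS = 1e-9

AXES = ("pitch", "yaw", "roll")


@dataclass(frozen=True)
class KRatios:
    """The three orientation slopes; ``None`` marks an undefined ratio."""

    kx: float | None
    ky: float | None
    kz: float | None


@dataclass(frozen=True)
class PoseAngles:
    """Per-frame Euler angles in degrees, each in (-90, 90) when defined.

    An undefined slope with a clearly signed numerator saturates to
    +/-90 deg; ``None`` means the angle could not be determined at all.
    """

    pitch_deg: float | None
    yaw_deg: float | None
    roll_deg: float | None

    def as_tuple(self) -> tuple[float | None, float | None, float | None]:
        return (self.pitch_deg, self.yaw_deg, self.roll_deg)


def _slope(num: float, den: float) -> float | None:
    if abs(den) < DENOM_EPS:
        return None
    return num / den


def k_ratios(kp: KeyPoints) -> KRatios:
    """Compute the three orientation slopes from the six key landmarks."""
    return KRatios(
        kx=_slope(kp.top_nose[2] - kp.bottom_nose[2], kp.top_nose[1] - kp.bottom_nose[1]),
        ky=_slope(kp.right_eye[2] - kp.left_eye[2], kp.right_eye[0] - kp.left_eye[0]),
        kz=_slope(kp.right_eye[1] - kp.left_eye[1], kp.right_eye[0] - kp.left_eye[0]),
    )


def _angle(k: float | None, num: float) -> float | None:
    if k is not None:
        return float(np.degrees(np.arctan(k)))
    # Degenerate denominator: saturate by numerator sign, or give up if the
    # numerator vanishes too.
    if abs(num) < DENOM_EPS:
        return None
    return 90.0 if num > 0 else -90.0


def angles_from_frame(frame: LandmarkFrame) -> PoseAngles | None:
    """Per-frame pose angles; ``None`` on a no-face frame."""
    kp = extract_key_points(frame)
    if kp is None:
        return None
    k = k_ratios(kp)
    return PoseAngles(
        pitch_deg=_angle(k.kx, kp.top_nose[2] - kp.bottom_nose[2]),
        yaw_deg=_angle(k.ky, kp.right_eye[2] - kp.left_eye[2]),
        roll_deg=_angle(k.kz, kp.right_eye[1] - kp.left_eye[1]),
    )


@dataclass
class AngleSeries:
    """Per-axis angle arrays (degrees) aligned to frames, with a validity mask."""

    fps: float
    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray
    valid: np.ndarray  # bool, per frame

    def __post_init__(self) -> None:
        n = len(self.pitch)
        if not (len(self.yaw) == len(self.roll) == len(self.valid) == n):
            raise ValueError("per-axis arrays must share one length")

    def __len__(self) -> int:
        return len(self.pitch)

    def axis(self, name: str) -> np.ndarray:
        return {"pitch": self.pitch, "yaw": self.yaw, "roll": self.roll}[name]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps


@dataclass
class VelocitySeries:
    """Per-axis angular-velocity arrays (degrees/second) with a validity mask."""

    fps: float
    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.pitch)

    def axis(self, name: str) -> np.ndarray:
        return {"pitch": self.pitch, "yaw": self.yaw, "roll": self.roll}[name]


def _valid_spans(valid: np.ndarray):
    """Yield (start, stop) half-open index ranges of contiguous valid frames."""
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _interpolate_gaps(values: np.ndarray, valid: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Fill invalid runs of length <= max_gap by linear interpolation.

    Only interior gaps (valid data on both sides) are filled; leading and
    trailing invalid runs stay invalid.
    """
    values = values.copy()
    valid = valid.copy()
    n = len(values)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            gap = j - i
            if 0 < i and j < n and gap <= max_gap:
                left, right = values[i - 1], values[j]
                for k in range(gap):
                    values[i + k] = left + (right - left) * (k + 1) / (gap + 1)
                valid[i:j] = True
            i = j
        else:
            i += 1
    return values, valid


def _moving_average(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average applied within each valid span.

    Near span edges the window shrinks symmetrically so no invalid sample
    leaks in and a constant signal stays constant.
    """
    if window <= 1:
        return values.copy()
    half = window // 2
    out = values.copy()
    for start, stop in _valid_spans(valid):
        seg = values[start:stop]
        m = len(seg)
        sm = np.empty(m)
        for i in range(m):
            h = min(half, i, m - 1 - i)
            sm[i] = seg[i - h : i + h + 1].mean()
        out[start:stop] = sm
    return out


def angle_series(
    seq: LandmarkSequence,
    smooth_window: int = 5,
    max_gap: int = 15,
) -> AngleSeries:
    """Compute the per-frame angle series of a landmark sequence.

    Parameters
    ----------
    seq
        Landmark sequence at constant fps.
    smooth_window
        Width (odd, frames) of the centered moving average applied within
        valid spans; 1 disables smoothing.  Default 5 frames at 30 fps,
        enough to suppress landmark jitter before differentiation without
        introducing phase lag.
    max_gap
        Longest run of no-face / undefined frames (frames) bridged by
        linear interpolation; longer gaps stay invalid.  Default 15
        (0.5 s at 30 fps).
    """
    if len(seq) == 0:
        raise ValueError("empty landmark sequence")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")

    n = len(seq)
    arrays = {ax: np.zeros(n) for ax in AXES}
    valids = {ax: np.zeros(n, dtype=bool) for ax in AXES}
    for i, frame in enumerate(seq):
        pa = angles_from_frame(frame)
        vals = pa.as_tuple() if pa is not None else (None, None, None)
        for ax, v in zip(AXES, vals):
            if v is not None:
                arrays[ax][i] = v
                valids[ax][i] = True

    for ax in AXES:
        arrays[ax], valids[ax] = _interpolate_gaps(arrays[ax], valids[ax], max_gap)
        arrays[ax] = _moving_average(arrays[ax], valids[ax], smooth_window)

    valid = valids["pitch"] & valids["yaw"] & valids["roll"]
    return AngleSeries(seq.fps, arrays["pitch"], arrays["yaw"], arrays["roll"], valid)


def angular_velocity(a: AngleSeries) -> VelocitySeries:
    """Differentiate an angle series into degrees/second.

    Interior valid frames use the central difference
    ``w[i] = (theta[i+1] - theta[i-1]) * fps / 2`` (second-order accurate);
    the first and last frame of each valid span use a one-sided difference.
    Frames whose stencil touches an invalid frame are invalid.
    """
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 frames to differentiate")
    out = {}
    vel_valid = np.zeros(n, dtype=bool)
    for ax in AXES:
        theta = a.axis(ax)
        w = np.zeros(n)
        for start, stop in _valid_spans(a.valid):
            m = stop - start
            if m == 1:
                continue
            seg = theta[start:stop]
            ws = np.empty(m)
            ws[1:-1] = (seg[2:] - seg[:-2]) * a.fps / 2.0
            ws[0] = (seg[1] - seg[0]) * a.fps
            ws[-1] = (seg[-1] - seg[-2]) * a.fps
            w[start:stop] = ws
            vel_valid[start:stop] = True
        out[ax] = w
    return VelocitySeries(a.fps, out["pitch"], out["yaw"], out["roll"], vel_valid)


def write_angle_series_csv(a: AngleSeries, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time_s", "pitch_deg", "yaw_deg", "roll_deg", "valid"])
        for i in range(len(a)):
            w.writerow(
                [i, f"{i / a.fps:.6f}", f"{a.pitch[i]:.6f}", f"{a.yaw[i]:.6f}",
                 f"{a.roll[i]:.6f}", int(a.valid[i])]
            )


def write_velocity_series_csv(v: VelocitySeries, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time_s", "pitch_dps", "yaw_dps", "roll_dps", "valid"])
        for i in range(len(v)):
            w.writerow(
                [i, f"{i / v.fps:.6f}", f"{v.pitch[i]:.6f}", f"{v.yaw[i]:.6f}",
                 f"{v.roll[i]:.6f}", int(v.valid[i])]
            )
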