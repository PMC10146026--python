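"""Data model and I/O for face-mesh landmark sequences.

The face mesh is a dense topology of 468 facial landmarks with normalized
image coordinates: ``x`` grows rightward and ``y`` downward, both in
``[0, 1]`` relative to the image size; ``z`` is depth in the detector's
landmark units, more negative toward the camera.  Six key landmarks drive
the head-pose angle formulas: the bottom and top of the nose bridge
(indices 2 and 6) and the four eye corners (33 and 133 for the left eye,
263 and 362 for the right eye), with each eye represented by the midpoint
of its two corners.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "N_LANDMARKS",
    "KEY_INDICES",
    "Sex",
    "Landmark",
    "LandmarkFrame",
    "LandmarkSequence",
    "KeyPoints",
    "FaceBox",
    "extract_key_points",
    "read_landmark_sequence",
    "write_landmark_sequence",
    "read_face_boxes",
    "write_face_boxes",
]

#: Number of points in a full face-mesh observation.
N_LANDMARKS = 468

#: Landmark indices used for head-pose estimation:
#: nose bottom, nose top, left-eye corners, right-eye corners.
KEY_INDICES = (2, 6, 33, 133, 263, 362)

#: Coordinates are stored with this many decimals; round-trip equality is
#: defined at this precision.
COORD_DECIMALS = 6


class Sex(str, Enum):
    """Subject sex, used to select normative range-of-motion standards."""

    MALE = "male"
    FEMALE = "female"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class Landmark:
    """One face-mesh point: index plus (x, y, z) coordinates."""

    index: int
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_LANDMARKS:
            raise ValueError(f"landmark index {self.index} outside [0, {N_LANDMARKS - 1}]")
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for landmark {self.index}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class LandmarkFrame:
    """One timestamped face-mesh observation: 468 points, or no face.

    Points are stored as a ``(468, 3)`` float array indexed by landmark
    index; a no-face frame has ``points is None``.
    """

    __slots__ = ("frame_index", "time_s", "points")

    def __init__(self, frame_index: int, time_s: float, points: np.ndarray | None):
        if frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if points is not None:
            points = np.asarray(points, dtype=float)
            if points.shape != (N_LANDMARKS, 3):
                raise ValueError(
                    f"frame {frame_index}: expected {N_LANDMARKS} landmarks, got shape {points.shape}"
                )
            if not np.all(np.isfinite(points)):
                raise ValueError(f"frame {frame_index}: non-finite landmark coordinates")
        self.frame_index = int(frame_index)
        self.time_s = float(time_s)
        self.points = points

    @property
    def has_face(self) -> bool:
        return self.points is not None

    @classmethod
    def from_landmarks(cls, frame_index: int, time_s: float, lms: Iterable[Landmark]) -> "LandmarkFrame":
        pts = np.full((N_LANDMARKS, 3), np.nan)
        seen: set[int] = set()
        for lm in lms:
            if lm.index in seen:
                raise ValueError(f"frame {frame_index}: duplicate landmark index {lm.index}")
            seen.add(lm.index)
            pts[lm.index] = (lm.x, lm.y, lm.z)
        if len(seen) != N_LANDMARKS:
            raise ValueError(
                f"frame {frame_index}: {len(seen)} landmarks present, expected {N_LANDMARKS}"
            )
        return cls(frame_index, time_s, pts)

    def __repr__(self) -> str:
        tag = "face" if self.has_face else "no-face"
        return f"LandmarkFrame(frame={self.frame_index}, t={self.time_s:.3f}s, {tag})"


@dataclass
class LandmarkSequence:
    """An ordered run of landmark frames sampled at constant fps."""

    fps: float
    frames: list[LandmarkFrame]
    subject_sex: Sex = Sex.UNSPECIFIED

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for i, f in enumerate(self.frames):
            if f.frame_index != i:
                raise ValueError(
                    f"frame indices must be contiguous from 0; position {i} holds index {f.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])


@dataclass(frozen=True)
class KeyPoints:
    """The six-landmark summary of a frame used for angle computation.

    ``left_eye`` and ``right_eye`` are the component-wise midpoints of the
    corner pairs (33, 133) and (263, 362); the nose points are landmarks 2
    and 6 verbatim.  Each is an (x, y, z) array.
    """

    bottom_nose: np.ndarray
    top_nose: np.ndarray
    left_eye: np.ndarray
    right_eye: np.ndarray


def extract_key_points(frame: LandmarkFrame) -> KeyPoints | None:
    """Select the six key landmarks of a frame; ``None`` on a no-face frame."""
    if not frame.has_face:
        return None
    p = frame.points
    return KeyPoints(
        bottom_nose=p[2].copy(),
        top_nose=p[6].copy(),
        left_eye=0.5 * (p[33] + p[133]),
        right_eye=0.5 * (p[263] + p[362]),
    )


@dataclass(frozen=True)
class FaceBox:
    """Half-open pixel box ``[x_left, x_right) x [y_top, y_bottom)`` on one frame."""

    frame_index: int
    x_left: int
    y_top: int
    x_right: int
    y_bottom: int

    def __post_init__(self) -> None:
        if self.x_left >= self.x_right or self.y_top >= self.y_bottom:
            raise ValueError(
                f"degenerate box on frame {self.frame_index}: "
                f"({self.x_left},{self.y_top})-({self.x_right},{self.y_bottom})"
            )

    @property
    def width(self) -> int:
        return self.x_right - self.x_left

    @property
    def height(self) -> int:
        return self.y_bottom - self.y_top


# ---------------------------------------------------------------------------
# CSV I/O
#
# Landmark CSV schema: header `frame,time_s,index,x,y,z`, 468 rows per
# present frame; frames absent from the file are no-face frames.
# ---------------------------------------------------------------------------

_LANDMARK_HEADER = ["frame", "time_s", "index", "x", "y", "z"]
_BOX_HEADER = ["frame", "x_left", "y_top", "x_right", "y_bottom"]


class LandmarkParseError(ValueError):
    """Raised when a landmark or box file does not conform to the schema."""


def write_landmark_sequence(seq: LandmarkSequence, path) -> None:
    """Write a sequence in the landmark CSV schema (6-decimal coordinates).

    No-face frames are represented by absence: they contribute no rows.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LANDMARK_HEADER)
        for frame in seq.frames:
            if not frame.has_face:
                continue
            t = f"{frame.time_s:.6f}"
            for idx in range(N_LANDMARKS):
                x, y, z = frame.points[idx]
                w.writerow([frame.frame_index, t, idx, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])


def read_landmark_sequence(path, fps: float, sex: Sex | str = Sex.UNSPECIFIED) -> LandmarkSequence:
    """Read a landmark CSV into a validated :class:`LandmarkSequence`.

    The file only stores frames in which a face was observed; the sequence
    is padded with explicit no-face frames so the time base stays uniform
    (missing frames between 0 and the last stored index become no-face).

    Raises
    ------
    LandmarkParseError
        On a malformed row (naming the line) or a frame with a wrong
        landmark count.
    """
    sex = Sex(sex)
    per_frame: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _LANDMARK_HEADER:
            raise LandmarkParseError(f"{path}: bad or missing header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                fi = int(row[0])
                idx = int(row[2])
                x, y, z = float(row[3]), float(row[4]), float(row[5])
            except (ValueError, IndexError) as exc:
                raise LandmarkParseError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if fi < 0:
                raise LandmarkParseError(f"{path}:{lineno}: negative frame index {fi}")
            if not 0 <= idx < N_LANDMARKS:
                raise LandmarkParseError(f"{path}:{lineno}: landmark index {idx} out of range")
            if fi not in per_frame:
                per_frame[fi] = np.full((N_LANDMARKS, 3), np.nan)
                counts[fi] = 0
            per_frame[fi][idx] = (x, y, z)
            counts[fi] += 1

    if not per_frame:
        raise LandmarkParseError(f"{path}: no landmark rows")
    for fi, n in counts.items():
        if n != N_LANDMARKS or np.isnan(per_frame[fi]).any():
            raise LandmarkParseError(
                f"{path}: frame {fi} has {n} landmark rows, expected {N_LANDMARKS}"
            )

    n_frames = max(per_frame) + 1
    frames = []
    for fi in range(n_frames):
        t = fi / fps
        frames.append(LandmarkFrame(fi, t, per_frame.get(fi)))
    return LandmarkSequence(fps=fps, frames=frames, subject_sex=sex)


def write_face_boxes(boxes: Sequence[FaceBox], path) -> None:
    """Write face boxes in the box CSV schema (pixels, half-open)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_BOX_HEADER)
        for b in boxes:
            w.writerow([b.frame_index, b.x_left, b.y_top, b.x_right, b.y_bottom])


def read_face_boxes(path) -> list[FaceBox]:
    """Read a face-box CSV; one box per listed frame."""
    out: list[FaceBox] = []
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _BOX_HEADER:
            raise LandmarkParseError(f"{path}: bad or missing header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out.append(FaceBox(*(int(v) for v in row[:5])))
            except (ValueError, IndexError) as exc:
                raise LandmarkParseError(f"{path}:{lineno}: malformed row {row!r}") from exc
    return out
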