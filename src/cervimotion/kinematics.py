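"""Repetition extremes of a cervical exercise recording.

A complete exercise visits six direction-sides — flexion and extension
(pitch), left and right axial rotation (yaw), left and right lateral
bending (roll) — three repetitions each.  For every direction-side this
module finds the repetition peaks of the signed angle series and, within
each peak's excursion, the peak angular speed, yielding the 18 amplitude
and 18 velocity extremes that the scoring formula consumes.

Side convention (matching the pose sign convention): side 1 of each axis
is flexion / left rotation / left bend, side 2 extension / right rotation
/ right bend.  With positive pitch = extension, positive yaw = left
rotation, positive roll = left bend, the signed-series sign of each side
is x1:-, x2:+, y1:+, y2:-, z1:+, z2:-.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import find_peaks

from .headpose import AngleSeries, VelocitySeries

__all__ = [
    "DIRECTION_SIDES",
    "SIDE_SIGN",
    "SIDE_AXIS",
    "N_REPS",
    "ExtremeSet",
    "find_extremes",
]

#: The six direction-sides in canonical order.
DIRECTION_SIDES = ("x1", "x2", "y1", "y2", "z1", "z2")

#: Angle-series axis backing each direction-side.
SIDE_AXIS: Mapping[str, str] = {
    "x1": "pitch", "x2": "pitch",
    "y1": "yaw", "y2": "yaw",
    "z1": "roll", "z2": "roll",
}

#: Sign of the signed angle series corresponding to each side.
SIDE_SIGN: Mapping[str, int] = {
    "x1": -1, "x2": +1,
    "y1": +1, "y2": -1,
    "z1": +1, "z2": -1,
}

#: Repetitions per direction-side in the exercise protocol.
N_REPS = 3


@dataclass
class ExtremeSet:
    """Top-``N_REPS`` amplitude and velocity extremes per direction-side.

    ``alpha[side]`` and ``omega[side]`` are length-3 lists of non-negative
    floats sorted descending, with ``None`` marking a missing repetition
    (fewer excursions detected than the protocol prescribes).
    """

    alpha: dict[str, list[float | None]]
    omega: dict[str, list[float | None]]

    def __post_init__(self) -> None:
        for side in DIRECTION_SIDES:
            for d in (self.alpha, self.omega):
                entries = d[side]
                if len(entries) != N_REPS:
                    raise ValueError(f"{side}: expected {N_REPS} entries")
                present = [e for e in entries if e is not None]
                if any(e < 0 for e in present):
                    raise ValueError(f"{side}: negative extreme")
                if present != sorted(present, reverse=True):
                    raise ValueError(f"{side}: extremes not sorted descending")

    def n_missing(self) -> int:
        return sum(
            e is None
            for d in (self.alpha, self.omega)
            for side in DIRECTION_SIDES
            for e in d[side]
        )

    def to_json(self, path=None) -> str:
        payload = {
            side: {"alpha": self.alpha[side], "omega": self.omega[side]}
            for side in DIRECTION_SIDES
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ExtremeSet":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            alpha={s: payload[s]["alpha"] for s in DIRECTION_SIDES},
            omega={s: payload[s]["omega"] for s in DIRECTION_SIDES},
        )


def _excursion_bounds(signed: np.ndarray, peak: int, lo: int, hi: int) -> tuple[int, int]:
    """Half-open bounds of the positive excursion containing ``peak``.

    The excursion extends from the last non-positive sample (or span start)
    before the peak to the first non-positive sample (or span end) after it.
    """
    i = peak
    while i > lo and signed[i - 1] > 0:
        i -= 1
    j = peak + 1
    while j < hi and signed[j] > 0:
        j += 1
    return i, j


def find_extremes(
    a: AngleSeries,
    v: VelocitySeries,
    min_prominence_deg: float = 5.0,
    min_separation_s: float = 1.0,
) -> ExtremeSet:
    """Extract per-repetition amplitude and velocity extremes.

    For each direction-side, local maxima of the signed angle series (the
    series negated for negative sides) with prominence at least
    ``min_prominence_deg`` and pairwise separation at least
    ``min_separation_s`` are candidate repetitions; the three largest are
    kept.  Each kept peak's excursion — the interval between the
    surrounding zero-crossings or valid-span ends — contributes its peak
    angular speed as the paired velocity extreme.  Direction-sides with
    fewer than three detected excursions report ``None`` for the missing
    repetitions.

    Raises
    ------
    ValueError
        If the series have mismatched lengths, no valid frames, or
        non-positive detection thresholds.
    """
    if len(a) != len(v):
        raise ValueError("angle and velocity series must be aligned")
    if min_prominence_deg <= 0 or min_separation_s <= 0:
        raise ValueError("detection thresholds must be positive")
    if not a.valid.any():
        raise ValueError("all frames invalid")

    distance = max(1, int(round(min_separation_s * a.fps)))
    alpha: dict[str, list[float | None]] = {}
    omega: dict[str, list[float | None]] = {}

    for side in DIRECTION_SIDES:
        theta = a.axis(SIDE_AXIS[side]) * SIDE_SIGN[side]
        speed = np.abs(v.axis(SIDE_AXIS[side]))

        amps: list[float] = []
        vels: list[float] = []
        # Peaks are searched within each contiguous valid span so an
        # invalid gap never produces a spurious excursion.
        for start, stop in _spans(a.valid):
            seg = theta[start:stop]
            peaks, _ = find_peaks(seg, prominence=min_prominence_deg, distance=distance)
            for p in peaks:
                if seg[p] <= 0:
                    continue
                lo, hi = _excursion_bounds(seg, p, 0, len(seg))
                vseg = speed[start + lo : start + hi]
                vmask = v.valid[start + lo : start + hi]
                vmax = float(vseg[vmask].max()) if vmask.any() else 0.0
                amps.append(float(seg[p]))
                vels.append(vmax)

        order = np.argsort(amps)[::-1][:N_REPS]
        kept_a = sorted((amps[i] for i in order), reverse=True)
        kept_w = sorted((vels[i] for i in order), reverse=True)
        pad = N_REPS - len(kept_a)
        alpha[side] = list(kept_a) + [None] * pad
        omega[side] = list(kept_w) + [None] * pad

    return ExtremeSet(alpha=alpha, omega=omega)


def _spans(valid: np.ndarray):
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
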