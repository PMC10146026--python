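"""Weighted range-of-motion and angular-velocity scoring.

The total score sums 36 score points: for each of the six direction-sides
(k in {x, y, z} crossed with side j in {1, 2}) and each of three
repetitions i, an amplitude term and a velocity term::

    score = sum_k sum_j sum_i [ min(a0_kj, a_kji)/a0_kj * a_kj
                              + min(w0_kj, w_kji)/w0_kj * b_kj ]

where a0/w0 are the standard amplitude (degrees) and standard peak
angular velocity (deg/s) for the direction-side, a_kji/w_kji the measured
extremes, and a_kj/b_kj dimensionless weighting factors.  A score point
earns its full weight once the measured extreme reaches the standard and
a proportional fraction below it.  With the default weights the
attainable total is 3 x (16.51 + 16.81) = 99.96 points, i.e. a nominal
full score of 100 up to the two-decimal rounding of the weights.

Reduced scoring standards (amplitude-only, velocity-only, single-axis and
axis-pair subsets) are selectable for ablation comparisons against the
full standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .kinematics import DIRECTION_SIDES, N_REPS, ExtremeSet
from .landmarks import Sex

__all__ = [
    "DEFAULT_WEIGHTS_A",
    "DEFAULT_WEIGHTS_B",
    "NORMATIVE_ROM_DEG",
    "ScoreWeights",
    "ScoreStandards",
    "ScoringStandardVariant",
    "ScorePoint",
    "ScoreReport",
    "score",
    "load_standard_profile",
    "load_weights",
]


class ConfigurationError(ValueError):
    """Raised for invalid weights or standards."""


#: Default weighting factors per direction-side (dimensionless points):
#: ``a`` weights amplitude score points, ``b`` velocity score points.
DEFAULT_WEIGHTS_A = {"x1": 2.25, "x2": 2.82, "y1": 2.90, "y2": 2.82, "z1": 2.90, "z2": 2.82}
DEFAULT_WEIGHTS_B = {"x1": 3.06, "x2": 3.09, "y1": 2.75, "y2": 2.58, "z1": 2.75, "z2": 2.58}

#: Normative cervical range of motion (degrees) per axis and sex.  Pitch
#: and yaw entries are total ranges across both sides; roll is per side.
NORMATIVE_ROM_DEG = {
    Sex.MALE: {"pitch": 68.0, "yaw": 145.0, "roll": 45.0},
    Sex.FEMALE: {"pitch": 76.0, "yaw": 139.0, "roll": 45.0},
}


@dataclass(frozen=True)
class ScoreWeights:
    """Per-direction-side weights for amplitude (``a``) and velocity (``b``)."""

    a: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS_A))
    b: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS_B))

    def __post_init__(self) -> None:
        for d, name in ((self.a, "a"), (self.b, "b")):
            if set(d) != set(DIRECTION_SIDES):
                raise ConfigurationError(f"weights '{name}' must cover {DIRECTION_SIDES}")
            if any(v <= 0 for v in d.values()):
                raise ConfigurationError(f"weights '{name}' must be positive")

    @property
    def max_total(self) -> float:
        """The attainable full score: N_REPS x (sum a + sum b)."""
        return N_REPS * (sum(self.a.values()) + sum(self.b.values()))


def _split_normative(sex: Sex) -> dict[str, float]:
    """Per-side standard amplitudes from the normative per-axis ranges.

    Flexion+extension and total axial rotation are conventionally quoted
    as sums over both sides, lateral bending per side; accordingly pitch
    and yaw totals are split equally between the two sides and roll is
    used per side as-is.  Explicit per-side values in a profile override
    this rule.
    """
    rom = NORMATIVE_ROM_DEG[sex]
    return {
        "x1": rom["pitch"] / 2, "x2": rom["pitch"] / 2,
        "y1": rom["yaw"] / 2, "y2": rom["yaw"] / 2,
        "z1": rom["roll"], "z2": rom["roll"],
    }


@dataclass(frozen=True)
class ScoreStandards:
    """Standard amplitude (deg) and peak velocity (deg/s) per direction-side."""

    alpha0: dict[str, float]
    omega0: dict[str, float]
    sex: Sex = Sex.UNSPECIFIED

    def __post_init__(self) -> None:
        for d, name in ((self.alpha0, "alpha0"), (self.omega0, "omega0")):
            if set(d) != set(DIRECTION_SIDES):
                raise ConfigurationError(f"standards '{name}' must cover {DIRECTION_SIDES}")
            if any(v <= 0 for v in d.values()):
                raise ConfigurationError(f"standards '{name}' must be positive")

    def to_json(self, path=None) -> str:
        payload = {"sex": self.sex.value, "alpha0": self.alpha0, "omega0": self.omega0}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


class ScoringStandardVariant(str, Enum):
    """Which subset of score-point terms is summed.

    ``FULL`` is the union of all amplitude and velocity terms; the other
    variants are ablations (amplitude-only, velocity-only, or both term
    kinds restricted to one or two axes).
    """

    ANGLE_ALL = "angle_all"
    ANGULAR_SPEED_ALL = "angular_speed_all"
    X = "x"
    Y = "y"
    Z = "z"
    XY = "xy"
    XZ = "xz"
    YZ = "yz"
    FULL = "full"

    def includes(self, term: str, side: str) -> bool:
        """Whether a score point (term 'alpha'|'omega' on a side) is summed."""
        axis_letter = side[0]  # 'x' | 'y' | 'z'
        if self is ScoringStandardVariant.FULL:
            return True
        if self is ScoringStandardVariant.ANGLE_ALL:
            return term == "alpha"
        if self is ScoringStandardVariant.ANGULAR_SPEED_ALL:
            return term == "omega"
        return axis_letter in self.value


@dataclass(frozen=True)
class ScorePoint:
    """One evaluated term of the scoring sum."""

    side: str
    rep: int  # 1-based repetition index
    term: str  # 'alpha' | 'omega'
    measured: float | None  # None when the repetition is missing
    standard: float
    weight: float
    ratio: float  # min(standard, measured)/standard, in [0, 1]
    awarded: float  # ratio * weight

    @property
    def missing(self) -> bool:
        return self.measured is None


@dataclass
class ScoreReport:
    """Full breakdown of one scoring evaluation."""

    variant: ScoringStandardVariant
    points: list[ScorePoint]
    total: float
    amplitude_subtotal: float
    velocity_subtotal: float
    side_subtotals: dict[str, float]
    max_total: float

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "total": self.total,
            "max_total": self.max_total,
            "amplitude_subtotal": self.amplitude_subtotal,
            "velocity_subtotal": self.velocity_subtotal,
            "side_subtotals": self.side_subtotals,
            "points": [
                {
                    "side": p.side,
                    "rep": p.rep,
                    "term": p.term,
                    "measured": p.measured,
                    "standard": p.standard,
                    "weight": p.weight,
                    "ratio": p.ratio,
                    "awarded": p.awarded,
                    "missing": p.missing,
                }
                for p in self.points
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def score(
    extremes: ExtremeSet,
    standards: ScoreStandards,
    weights: ScoreWeights | None = None,
    variant: ScoringStandardVariant = ScoringStandardVariant.FULL,
) -> ScoreReport:
    """Evaluate the scoring sum over the variant's score points.

    Missing repetitions contribute 0 and are flagged in the report,
    distinct from a measured zero.
    """
    weights = weights or ScoreWeights()
    points: list[ScorePoint] = []
    for side in DIRECTION_SIDES:
        for term, values, std, wmap in (
            ("alpha", extremes.alpha[side], standards.alpha0[side], weights.a),
            ("omega", extremes.omega[side], standards.omega0[side], weights.b),
        ):
            if not variant.includes(term, side):
                continue
            for i, measured in enumerate(values, start=1):
                ratio = 0.0 if measured is None else min(std, measured) / std
                w = wmap[side]
                points.append(
                    ScorePoint(
                        side=side, rep=i, term=term, measured=measured,
                        standard=std, weight=w, ratio=ratio, awarded=ratio * w,
                    )
                )

    total = sum(p.awarded for p in points)
    amp = sum(p.awarded for p in points if p.term == "alpha")
    vel = sum(p.awarded for p in points if p.term == "omega")
    side_totals = {
        s: sum(p.awarded for p in points if p.side == s) for s in DIRECTION_SIDES
    }
    return ScoreReport(
        variant=variant,
        points=points,
        total=total,
        amplitude_subtotal=amp,
        velocity_subtotal=vel,
        side_subtotals=side_totals,
        max_total=weights.max_total,
    )


def load_weights(path) -> ScoreWeights:
    """Load weights from JSON ``{"a": {side: value, ...}, "b": {...}}``."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        return ScoreWeights(a=dict(payload["a"]), b=dict(payload["b"]))
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing weights section {exc}") from exc


def load_standard_profile(path) -> ScoreStandards:
    """Load a standards profile from JSON.

    Schema: ``{"sex": "male"|"female"|"unspecified", "alpha0": {...}?,
    "omega0": {...}}``.  ``omega0`` is required — standard velocities come
    from a standard exercise recording and have no normative table.  An
    omitted ``alpha0`` defaults to the normative per-axis ranges for the
    profile's sex, split per side.
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    sex = Sex(payload.get("sex", "unspecified"))
    if "omega0" not in payload:
        raise ConfigurationError(f"{path}: 'omega0' is required (no normative default exists)")
    omega0 = {k: float(v) for k, v in payload["omega0"].items()}
    if "alpha0" in payload and payload["alpha0"] is not None:
        alpha0 = {k: float(v) for k, v in payload["alpha0"].items()}
    else:
        if sex is Sex.UNSPECIFIED:
            raise ConfigurationError(
                f"{path}: 'alpha0' omitted and sex unspecified; no normative default applies"
            )
        alpha0 = _split_normative(sex)
    return ScoreStandards(alpha0=alpha0, omega0=omega0, sex=sex)


def default_standards(sex: Sex, omega0: dict[str, float]) -> ScoreStandards:
    """Standards from the normative amplitude table plus explicit velocities."""
    return ScoreStandards(alpha0=_split_normative(sex), omega0=dict(omega0), sex=sex)
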