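import json

import numpy as np
import pytest

from cervimotion.kinematics import DIRECTION_SIDES, ExtremeSet
from cervimotion.scoring import (
    ConfigurationError,
    ScoreStandards,
    ScoreWeights,
    ScoringStandardVariant,
    load_standard_profile,
    load_weights,
    score,
)


def make_standards(alpha=30.0, omega=40.0):
    return ScoreStandards(
        alpha0={s: alpha for s in DIRECTION_SIDES},
        omega0={s: omega for s in DIRECTION_SIDES},
    )


def make_extremes(alpha, omega):
    return ExtremeSet(
        alpha={s: [alpha] * 3 for s in DIRECTION_SIDES},
        omega={s: [omega] * 3 for s in DIRECTION_SIDES},
    )


def random_extremes(rng, scale=60.0):
    def triple():
        return sorted(rng.uniform(0, scale, 3).tolist(), reverse=True)

    return ExtremeSet(
        alpha={s: triple() for s in DIRECTION_SIDES},
        omega={s: triple() for s in DIRECTION_SIDES},
    )


def test_full_marks_total_is_weight_sum_times_reps():
    """All 36 extremes at standard: total = 3 x (sum a + sum b) = 99.96."""
    w = ScoreWeights()
    oracle = 3 * (sum(w.a.values()) + sum(w.b.values()))
    report = score(make_extremes(30.0, 40.0), make_standards())
    assert report.total == pytest.approx(oracle, abs=1e-9)
    assert report.total == pytest.approx(99.96, abs=1e-9)


def test_zero_extremes_score_zero():
    assert score(make_extremes(0.0, 0.0), make_standards()).total == 0.0


def test_single_half_standard_amplitude_term():
    """Only the first flexion amplitude at half standard: 0.5 x a_x1 = 1.125."""
    ext = make_extremes(0.0, 0.0)
    ext.alpha["x1"][0] = 15.0  # standard 30
    report = score(ext, make_standards())
    assert report.total == pytest.approx(0.5 * 2.25)
    assert report.side_subtotals["x1"] == pytest.approx(1.125)


def test_variant_additivity():
    """angle_all + angular_speed_all = full, for arbitrary extremes."""
    rng = np.random.default_rng(12)
    std = make_standards()
    for _ in range(5):
        ext = random_extremes(rng)
        full = score(ext, std, variant=ScoringStandardVariant.FULL).total
        parts = (
            score(ext, std, variant=ScoringStandardVariant.ANGLE_ALL).total
            + score(ext, std, variant=ScoringStandardVariant.ANGULAR_SPEED_ALL).total
        )
        assert parts == pytest.approx(full, abs=1e-9)


def test_axis_variants_partition_the_full_score():
    rng = np.random.default_rng(99)
    std = make_standards()
    ext = random_extremes(rng)
    singles = sum(
        score(ext, std, variant=v).total
        for v in (ScoringStandardVariant.X, ScoringStandardVariant.Y, ScoringStandardVariant.Z)
    )
    assert singles == pytest.approx(score(ext, std).total, abs=1e-9)
    xy = score(ext, std, variant=ScoringStandardVariant.XY).total
    x = score(ext, std, variant=ScoringStandardVariant.X).total
    y = score(ext, std, variant=ScoringStandardVariant.Y).total
    assert xy == pytest.approx(x + y, abs=1e-9)


def test_monotone_and_saturating_in_each_extreme():
    std = make_standards(alpha=30.0)
    prev = -1.0
    for val in (0.0, 10.0, 20.0, 30.0, 50.0, 80.0):
        ext = make_extremes(0.0, 0.0)
        ext.alpha["y1"][0] = val
        total = score(ext, std).total
        assert total >= prev
        prev = total
    at_std = make_extremes(0.0, 0.0)
    at_std.alpha["y1"][0] = 30.0
    above = make_extremes(0.0, 0.0)
    above.alpha["y1"][0] = 300.0
    assert score(at_std, std).total == pytest.approx(score(above, std).total)


def test_homogeneity_under_joint_rescaling():
    rng = np.random.default_rng(4)
    ext = random_extremes(rng)
    s1 = score(ext, make_standards(30.0, 40.0)).total
    doubled = ExtremeSet(
        alpha={s: [2 * v for v in ext.alpha[s]] for s in DIRECTION_SIDES},
        omega={s: [2 * v for v in ext.omega[s]] for s in DIRECTION_SIDES},
    )
    s2 = score(doubled, make_standards(60.0, 80.0)).total
    assert s2 == pytest.approx(s1, abs=1e-9)


def test_missing_extremes_contribute_zero_and_are_flagged():
    ext = make_extremes(30.0, 40.0)
    ext.alpha["z2"][2] = None
    report = score(ext, make_standards())
    assert report.total == pytest.approx(99.96 - 2.82, abs=1e-9)
    flagged = [p for p in report.points if p.missing]
    assert len(flagged) == 1 and flagged[0].side == "z2" and flagged[0].term == "alpha"


def test_nonpositive_standard_rejected():
    with pytest.raises(ConfigurationError):
        ScoreStandards(
            alpha0={s: 30.0 for s in DIRECTION_SIDES},
            omega0={**{s: 40.0 for s in DIRECTION_SIDES}, "x1": -5.0},
        )


class TestProfileLoading:
    def test_normative_default_splits_rotation_total(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps(
            {"sex": "male", "omega0": {s: 40.0 for s in DIRECTION_SIDES}}))
        std = load_standard_profile(path)
        assert std.alpha0["y1"] == std.alpha0["y2"] == pytest.approx(72.5)
        assert std.alpha0["x1"] == pytest.approx(34.0)
        assert std.alpha0["z1"] == pytest.approx(45.0)  # bending quoted per side

    def test_female_normative_default(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps(
            {"sex": "female", "omega0": {s: 40.0 for s in DIRECTION_SIDES}}))
        std = load_standard_profile(path)
        assert std.alpha0["x1"] == pytest.approx(38.0)
        assert std.alpha0["y1"] == pytest.approx(69.5)

    def test_explicit_alpha0_passes_through(self, tmp_path):
        path = tmp_path / "p.json"
        alpha = {s: 10.0 + i for i, s in enumerate(DIRECTION_SIDES)}
        path.write_text(json.dumps(
            {"sex": "male", "alpha0": alpha,
             "omega0": {s: 40.0 for s in DIRECTION_SIDES}}))
        assert load_standard_profile(path).alpha0 == alpha

    def test_missing_omega0_is_an_error(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps({"sex": "male"}))
        with pytest.raises(ConfigurationError, match="omega0"):
            load_standard_profile(path)

    def test_negative_omega0_is_an_error(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps(
            {"sex": "male",
             "omega0": {**{s: 40.0 for s in DIRECTION_SIDES}, "x1": -5.0}}))
        with pytest.raises(ConfigurationError):
            load_standard_profile(path)


def test_weights_json_round_trip(tmp_path):
    w = ScoreWeights()
    path = tmp_path / "w.json"
    path.write_text(json.dumps({"a": w.a, "b": w.b}))
    back = load_weights(path)
    assert back.a == w.a and back.b == w.b
    assert back.max_total == pytest.approx(99.96)
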