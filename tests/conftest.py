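import numpy as np
import pytest

from cervimotion import headpose, kinematics, synthmotion
from cervimotion.landmarks import Sex


@pytest.fixture(scope="session")
def template():
    return synthmotion.canonical_template()


@pytest.fixture(scope="session")
def male_plan():
    """Standard exercise plan at the male normative amplitudes."""
    return synthmotion.standard_plan(Sex.MALE)


@pytest.fixture(scope="session")
def male_profile(male_plan):
    """Scoring standards measured from the noiseless standard rendering."""
    return synthmotion.reference_standard_profile(male_plan, Sex.MALE)


@pytest.fixture(scope="session")
def male_pipeline(male_plan):
    """(sequence, angle series, velocity series, extremes) of the standard plan."""
    seq = synthmotion.generate_sequence(male_plan, sex=Sex.MALE)
    a = headpose.angle_series(seq)
    v = headpose.angular_velocity(a)
    ext = kinematics.find_extremes(a, v)
    return seq, a, v, ext


def render_static(pitch=0.0, yaw=0.0, roll=0.0, n=3, fps=30.0, noise_sd=0.0, seed=0):
    """Landmark sequence holding one fixed pose for n frames."""
    gt = synthmotion.GroundTruth(
        fps=fps,
        pitch=np.full(n, float(pitch)),
        yaw=np.full(n, float(yaw)),
        roll=np.full(n, float(roll)),
    )
    return synthmotion.render_landmarks(gt, noise_sd=noise_sd, seed=seed)
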