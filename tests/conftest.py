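import numpy as np
import pytest

import magbehave as mb
from magbehave.io import PipelineConfig
from magbehave.pipeline import recordings_to_features
from magbehave.simulate import BehaviourProfile, DEFAULT_PROFILES


@pytest.fixture(scope="session")
def field():
    """Study-site field: 27.3 μT, dip 65° upward, declination 17.9° W."""
    return mb.make_earth_field(27.3, 65.0, -17.9)


@pytest.fixture(scope="session")
def still_profiles():
    """Tremor-free profiles: ideal geometry for closed-form checks."""
    profiles = dict(DEFAULT_PROFILES)
    profiles["vigilance"] = BehaviourProfile("vigilance", 90.0, 0.0, 0.0)
    profiles["resting"] = BehaviourProfile("resting", -90.0, 0.0, 0.0)
    return profiles


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_features(config):
    """Feature matrix from a small 3-individual, 2-session dataset."""
    recs = mb.simulate_dataset(3, 2, seed=5, session_minutes=10.0)
    return recordings_to_features(recs, config)


@pytest.fixture(scope="session")
def study_features(config):
    """Feature matrix from the full 11-session study-structured dataset."""
    recs = mb.make_study_dataset(seed=1)
    return recordings_to_features(recs, config)


@pytest.fixture(scope="session")
def study_selection(study_features):
    return mb.select_descriptor_features(study_features)


@pytest.fixture()
def gaussian_fm():
    """Hand-built separable feature matrix in the three-descriptor space.

    Class geometry mimics the biomechanical layout: vigilance high
    +posture/low intensity, resting low −posture/low intensity, foraging
    mid posture/mid intensity/low periodicity, running high intensity and
    periodicity.
    """
    from tests_support import balanced_gaussian_fm

    return balanced_gaussian_fm(n_per_class=50)


@pytest.fixture(scope="session")
def three_feature_selection():
    return {"posture": "meanRoll", "intensity": "meanAbsDiffRoll",
            "periodicity": "avgDiffFftPeakPower"}
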