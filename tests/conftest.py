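import numpy as np
import pytest

from wriststep.classifier import TrainConfig
from wriststep.pipeline import AnnotatedRecording
from wriststep.synthetic import GaitProfile, make_fixture_cohort, simulate_participant


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def oxwalk_cohort():
    """Ten 1-h free-living-like participants; shared across modules."""
    return make_fixture_cohort(10, preset="oxwalk_like", seed=42)


@pytest.fixture(scope="session")
def annotated_items(oxwalk_cohort):
    return [
        AnnotatedRecording(r.recording, r.truth_steps.times) for r in oxwalk_cohort
    ]


@pytest.fixture(scope="session")
def clean_walk_recording():
    """Sedentary / 60-s clean walk at 100 steps/min / sedentary, 25 Hz."""
    profile = GaitProfile(cadence_spm=100, cadence_jitter=0.0, noise_sd_g=0.0)
    return simulate_participant(
        [("sedentary", None, 30.0), ("walk", profile, 60.0), ("sedentary", None, 30.0)],
        sample_rate_hz=25.0,
        seed=7,
    )


@pytest.fixture
def train_config():
    return TrainConfig(seed=11)
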