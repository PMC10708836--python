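import numpy as np
import pytest

from mfnet.skeleton_core import SkeletonSequence
from mfnet.synthetic_actions import five_class_spec, generate, two_class_spec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_frame(rng):
    """One plausible 20-joint frame (meters-scale coordinates)."""
    return rng.normal(scale=0.5, size=(20, 3)) + np.array([0, 0, 1.0])


@pytest.fixture
def short_sequence(rng):
    coords = rng.normal(scale=0.3, size=(12, 20, 3))
    return SkeletonSequence(coords=coords, label=0, sample_id="test")


@pytest.fixture(scope="session")
def two_class_dataset():
    """Small frozen 2-class dataset shared across training tests."""
    sequences, manifest = generate(two_class_spec(seed=5))
    return sequences, manifest.labels()


@pytest.fixture(scope="session")
def five_class_dataset():
    """The frozen 5-class desk fixture: 500 samples, seed 3."""
    sequences, manifest = generate(five_class_spec(seed=3))
    return sequences, manifest.labels()
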