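import numpy as np
import pytest

from infantmotion import N_KEYPOINTS, SkeletonSequence
from infantmotion.clips import Clip, segment_clips
from infantmotion.config import preprocess_sequence
from infantmotion.simulate import SimulationParams, simulate_sequence


def make_sequence(
    xy: np.ndarray,
    confidence: np.ndarray | None = None,
    visible: np.ndarray | None = None,
    fps: float = 15.0,
    units: str = "pixels",
    **kwargs,
) -> SkeletonSequence:
    """Build a sequence from an (T, 17, 2) array with full defaults."""
    xy = np.asarray(xy, dtype=float)
    if confidence is None:
        confidence = np.ones(xy.shape[:2])
    if visible is None:
        visible = confidence > 0
    return SkeletonSequence(
        xy=xy, confidence=confidence, visible=visible, fps=fps, units=units, **kwargs
    )


def random_sequence(rng: np.random.Generator, n_frames: int = 30) -> SkeletonSequence:
    xy = rng.uniform(0, 500, size=(n_frames, N_KEYPOINTS, 2))
    conf = rng.uniform(0.05, 1.0, size=(n_frames, N_KEYPOINTS))
    return make_sequence(xy, conf, subject_id="rand")


def make_clip(xy: np.ndarray, fps: float = 15.0, **kwargs) -> Clip:
    return Clip(xy=np.asarray(xy, dtype=float), fps=fps,
                subject_id=kwargs.pop("subject_id", "test"),
                start_frame=kwargs.pop("start_frame", 0), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noiseless_params():
    """Simulator settings without noise, dropout, or rigid-body drift."""
    return SimulationParams(
        noise_sd=0.0, missing_prob=0.0, low_conf_prob=0.0,
        drift_rotation=0.0, drift_translation=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def simulated_clip(noiseless_params):
    """One qualifying normalized clip from a noiseless typical subject."""
    seq = simulate_sequence(noiseless_params, label="typical", subject_id="fix000")
    clips = segment_clips(preprocess_sequence(seq))
    assert clips, "fixture sequence must yield at least one clip"
    return clips[0]
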