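"""Fixed-length clip segmentation and activity gating.

Normalized sequences are cut into non-overlapping 15 s clips; only clips in
which the infant is sufficiently active — mean distal-joint movement speed
strictly above 0.9 trunk lengths per second — enter feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import KEYPOINT_INDEX, TRUNK_LENGTHS, SkeletonSequence

__all__ = [
    "Clip",
    "DISTAL_JOINTS",
    "DISTAL_INDICES",
    "segment_clips",
    "mean_movement_speed",
    "select_active_clips",
    "velocities",
]

# The freely moving limb joints that carry the classification signal; the
# shoulders and hips serve as anchors of the normalized frame and are
# excluded from the activity score.
DISTAL_JOINTS: tuple[str, ...] = (
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)
DISTAL_INDICES = np.array([KEYPOINT_INDEX[j] for j in DISTAL_JOINTS])

DEFAULT_CLIP_SECONDS = 15.0
DEFAULT_SPEED_THRESHOLD = 0.9  # trunk lengths per second


@dataclass
class Clip:
    """A contiguous fixed-duration segment of a normalized sequence."""

    xy: np.ndarray  # (n_frames, 17, 2), trunk-length units
    fps: float
    subject_id: str
    start_frame: int
    label: str | None = None
    mean_speed: float | None = None
    qualifies: bool | None = None

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def clip_id(self) -> str:
        return f"{self.subject_id}:{self.start_frame}"


def velocities(xy: np.ndarray, fps: float) -> np.ndarray:
    """Forward-difference velocity vectors, trunk lengths per second.

    v_t = (p_{t+1} - p_t) * fps; the last frame copies its predecessor's
    velocity so the series has one value per frame.
    """
    v = np.diff(xy, axis=0) * fps
    if len(v) == 0:
        return np.zeros_like(xy)
    return np.concatenate([v, v[-1:]], axis=0)


def segment_clips(
    seq: SkeletonSequence, clip_seconds: float = DEFAULT_CLIP_SECONDS
) -> list[Clip]:
    """Cut a normalized sequence into consecutive non-overlapping clips.

    Each clip spans ``round(clip_seconds * fps)`` frames from the sequence
    start; a trailing remainder shorter than one clip is discarded.  A
    sequence shorter than one clip yields an empty list.
    """
    if seq.units != TRUNK_LENGTHS:
        raise ValueError("segment_clips requires a normalized sequence")
    n = int(round(clip_seconds * seq.fps))
    if n <= 0:
        raise ValueError("clip length must be at least one frame")
    clips = []
    for start in range(0, seq.n_frames - n + 1, n):
        clip = Clip(
            xy=seq.xy[start : start + n].copy(),
            fps=seq.fps,
            subject_id=seq.subject_id,
            start_frame=start,
            label=seq.label,
        )
        clip.mean_speed = mean_movement_speed(clip)
        clips.append(clip)
    return clips


def mean_movement_speed(clip: Clip) -> float:
    """Mean instantaneous speed of the 8 distal joints, trunk lengths/s.

    The per-frame speeds (Euclidean norms of forward-difference velocities)
    of the elbows, wrists, knees and ankles are averaged over joints and
    frames.
    """
    v = velocities(clip.xy[:, DISTAL_INDICES], clip.fps)
    return float(np.linalg.norm(v, axis=-1).mean())


def cumulative_mean_speed(clip: Clip) -> np.ndarray:
    """Running mean of the per-frame distal-joint speed (for reporting)."""
    v = velocities(clip.xy[:, DISTAL_INDICES], clip.fps)
    per_frame = np.linalg.norm(v, axis=-1).mean(axis=1)
    return np.cumsum(per_frame) / np.arange(1, len(per_frame) + 1)


def select_active_clips(
    clips: list[Clip], threshold: float = DEFAULT_SPEED_THRESHOLD
) -> list[Clip]:
    """Retain clips whose mean movement speed is strictly above ``threshold``.

    Sets the ``qualifies`` flag on every input clip and returns the
    qualifying subset in input order.
    """
    selected = []
    for clip in clips:
        if clip.mean_speed is None:
            clip.mean_speed = mean_movement_speed(clip)
        clip.qualifies = clip.mean_speed > threshold
        if clip.qualifies:
            selected.append(clip)
    return selected
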