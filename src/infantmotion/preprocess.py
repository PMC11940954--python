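"""Temporal smoothing and camera-invariant spatial normalization.

Raw detector output lives in pixel coordinates that depend on camera
distance, placement, and roll.  Normalization maps every frame into a
body-centred frame: the shoulder midpoint is the origin, the trunk
(shoulder midpoint -> hip midpoint) points along +y, and all coordinates
are expressed in units of that frame's trunk length.  The result is
invariant to global translation, rotation, and uniform scaling of the
input, which makes kinematic features comparable across recordings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .skeleton import KEYPOINT_INDEX, TRUNK_LENGTHS, SkeletonSequence

__all__ = ["smooth", "normalize", "DegenerateFrameError", "trunk_lengths"]

L_SHOULDER = KEYPOINT_INDEX["left_shoulder"]
R_SHOULDER = KEYPOINT_INDEX["right_shoulder"]
L_HIP = KEYPOINT_INDEX["left_hip"]
R_HIP = KEYPOINT_INDEX["right_hip"]

DEFAULT_SMOOTHING_WINDOW = 5


class DegenerateFrameError(ValueError):
    """A frame's trunk length is zero; the skeleton cannot be normalized."""


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean along axis 0 with symmetric truncation at the ends.

    Frame t averages frames [t-h, t+h] intersected with the sequence, so the
    first/last frames use shorter windows instead of being dropped.
    """
    n = x.shape[0]
    h = window // 2
    csum = np.cumsum(x, axis=0)
    zero = np.zeros((1,) + x.shape[1:], dtype=x.dtype)
    csum = np.concatenate([zero, csum], axis=0)
    t = np.arange(n)
    lo = np.maximum(t - h, 0)
    hi = np.minimum(t + h, n - 1) + 1
    counts = (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    return (csum[hi] - csum[lo]) / counts


def smooth(seq: SkeletonSequence, window: int = DEFAULT_SMOOTHING_WINDOW) -> SkeletonSequence:
    """Apply a centred rolling-mean filter of width ``window`` frames.

    Reduces frame-to-frame jitter from per-frame pose estimation.  The
    window must be odd so the filter is symmetric and introduces no lag;
    it is truncated (not padded) at the sequence boundaries.

    Raises
    ------
    ValueError
        If the sequence has missing keypoints, the window is even, or the
        window exceeds the sequence length.
    """
    if not seq.is_complete():
        raise ValueError("smooth requires a complete sequence; interpolate first")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window > seq.n_frames:
        raise ValueError(
            f"smoothing window {window} exceeds sequence length {seq.n_frames}"
        )
    out = seq.copy()
    out.xy = _rolling_mean(seq.xy, window)
    return out


def _midpoints(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shoulder_mid = 0.5 * (xy[:, L_SHOULDER] + xy[:, R_SHOULDER])
    hip_mid = 0.5 * (xy[:, L_HIP] + xy[:, R_HIP])
    return shoulder_mid, hip_mid


def trunk_lengths(seq: SkeletonSequence) -> np.ndarray:
    """Per-frame trunk length: shoulder midpoint to hip midpoint distance."""
    shoulder_mid, hip_mid = _midpoints(seq.xy)
    return np.linalg.norm(hip_mid - shoulder_mid, axis=1)


def normalize(seq: SkeletonSequence) -> SkeletonSequence:
    """Map each frame to the trunk-anchored, trunk-scaled reference frame.

    Per frame: translate the shoulder midpoint to the origin, rotate so the
    trunk vector (shoulder midpoint -> hip midpoint) lies along +y (downward
    in image convention), and divide by the trunk length.  A proper rotation
    is used, so left/right laterality is preserved.

    Raises
    ------
    DegenerateFrameError
        If any frame's trunk length is zero.
    ValueError
        If the sequence has missing keypoints.
    """
    if not seq.is_complete():
        raise ValueError("normalize requires a complete sequence; interpolate first")
    shoulder_mid, hip_mid = _midpoints(seq.xy)
    trunk = hip_mid - shoulder_mid
    length = np.linalg.norm(trunk, axis=1)
    bad = np.flatnonzero(length <= 0)
    if bad.size:
        raise DegenerateFrameError(
            f"subject {seq.subject_id!r}: zero trunk length in frame {bad[0]}"
        )
    u = trunk / length[:, None]  # unit trunk direction per frame
    # Rotation sending u to (0, 1): rows (u_y, -u_x) and (u_x, u_y).
    centred = seq.xy - shoulder_mid[:, None, :]
    x_new = centred[..., 0] * u[:, None, 1] - centred[..., 1] * u[:, None, 0]
    y_new = centred[..., 0] * u[:, None, 0] + centred[..., 1] * u[:, None, 1]
    out = seq.copy()
    out.xy = np.stack([x_new, y_new], axis=-1) / length[:, None, None]
    return replace(out, units=TRUNK_LENGTHS)
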