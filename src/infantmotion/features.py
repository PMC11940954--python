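"""The fixed catalog of 227 kinematic, motion, and posture features per clip.

Feature blocks (counts in parentheses; 8 distal joints = elbows, wrists,
knees, ankles; 8 angle joints = shoulders, elbows, hips, knees):

1.  distal speed mean + max                            (16)
2.  distal acceleration mean + max                     (16)
3.  distal speed entropy                               (8)
4.  distal acceleration entropy                        (8)
5.  distal segment angular velocity mean + max         (16)
6.  distal segment angular acceleration mean + max     (16)
7.  joint angles x {mean, max, min, std, range}        (40)
8.  joint angular velocity x {mean, max, std}          (24)
9.  joint angular acceleration x {mean, max, std}      (24)
10. pairwise windowed correlations of the 8 angle joints'
    speed and acceleration series, C(8,2) x 2          (56)
11. whole-body mean speed, mean acceleration,
    speed entropy                                      (3)

Total 227.  This catalog is the package's normative feature definition.

All kinematics are computed on normalized clips (trunk-length units), so
every feature is invariant to camera placement.  Derivatives use forward
differences at the clip frame rate; angle statistics use magnitudes;
entropies use 10 equal-width bins on the series' own range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

import pandas as pd

from .clips import DISTAL_INDICES, DISTAL_JOINTS, Clip, velocities
from .skeleton import KEYPOINT_INDEX

__all__ = [
    "ANGLE_JOINTS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "FeatureVector",
    "speed_series",
    "acceleration_series",
    "joint_angles",
    "windowed_correlation",
    "histogram_entropy",
    "extract_features",
    "features_table",
]

# Joints with a defined interior angle (the wrists/ankles have none: they
# terminate the chain, so they carry segment-orientation kinematics instead).
ANGLE_JOINTS: tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
)

# Parent joint of the segment that ends at each distal joint: upper arm for
# the elbow, forearm for the wrist, thigh for the knee, shank for the ankle.
SEGMENT_PARENT: dict[str, str] = {
    "left_elbow": "left_shoulder",
    "right_elbow": "right_shoulder",
    "left_wrist": "left_elbow",
    "right_wrist": "right_elbow",
    "left_knee": "left_hip",
    "right_knee": "right_hip",
    "left_ankle": "left_knee",
    "right_ankle": "right_knee",
}

DEFAULT_ENTROPY_BINS = 10
DEFAULT_CORRELATION_WINDOW = 5
_CONST_TOL = 1e-12


def _build_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for j in DISTAL_JOINTS:  # blocks 1-2
        names += [f"{j}_speed_mean", f"{j}_speed_max"]
    for j in DISTAL_JOINTS:
        names += [f"{j}_accel_mean", f"{j}_accel_max"]
    names += [f"{j}_speed_entropy" for j in DISTAL_JOINTS]  # block 3
    names += [f"{j}_accel_entropy" for j in DISTAL_JOINTS]  # block 4
    for j in DISTAL_JOINTS:  # blocks 5-6
        names += [f"{j}_segment_angvel_mean", f"{j}_segment_angvel_max"]
    for j in DISTAL_JOINTS:
        names += [f"{j}_segment_angacc_mean", f"{j}_segment_angacc_max"]
    for j in ANGLE_JOINTS:  # block 7
        names += [f"{j}_angle_{s}" for s in ("mean", "max", "min", "std", "range")]
    for j in ANGLE_JOINTS:  # block 8
        names += [f"{j}_angvel_{s}" for s in ("mean", "max", "std")]
    for j in ANGLE_JOINTS:  # block 9
        names += [f"{j}_angacc_{s}" for s in ("mean", "max", "std")]
    for a, b in combinations(ANGLE_JOINTS, 2):  # block 10
        names.append(f"corr_speed_{a}_{b}")
    for a, b in combinations(ANGLE_JOINTS, 2):
        names.append(f"corr_accel_{a}_{b}")
    names += ["whole_body_speed_mean", "whole_body_accel_mean", "whole_body_speed_entropy"]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 227


@dataclass
class FeatureVector:
    """Named vector of exactly 227 scalar features for one clip."""

    values: np.ndarray  # (227,)
    clip_ref: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


# ---------------------------------------------------------------------------
# Elementary series
# ---------------------------------------------------------------------------


def speed_series(clip: Clip, joint: str) -> np.ndarray:
    """Per-frame speed of one joint, trunk lengths per second."""
    v = velocities(clip.xy[:, KEYPOINT_INDEX[joint]], clip.fps)
    return np.linalg.norm(v, axis=-1)


def acceleration_series(clip: Clip, joint: str) -> np.ndarray:
    """Per-frame acceleration magnitude of one joint, trunk lengths / s^2."""
    v = velocities(clip.xy[:, KEYPOINT_INDEX[joint]], clip.fps)
    a = _series_derivative(v, clip.fps)
    return np.linalg.norm(a, axis=-1)


def _all_velocities(clip: Clip) -> np.ndarray:
    """(T, 17, 2) forward-difference velocities for every keypoint."""
    return velocities(clip.xy, clip.fps)


def _series_derivative(x: np.ndarray, fps: float) -> np.ndarray:
    """Forward difference x fps along axis 0, last value copied."""
    d = np.diff(x, axis=0) * fps
    return np.concatenate([d, d[-1:]], axis=0)


# ---------------------------------------------------------------------------
# Joint angles
# ---------------------------------------------------------------------------

# vertex -> (ray_a endpoint or "trunk", ray_b endpoint).  "trunk" denotes the
# caudal trunk direction (shoulder midpoint -> hip midpoint), the reference
# for shoulder and hip angles.
_ANGLE_DEFS: dict[str, tuple[str, str]] = {
    "left_shoulder": ("trunk", "left_elbow"),
    "right_shoulder": ("trunk", "right_elbow"),
    "left_elbow": ("left_shoulder", "left_wrist"),
    "right_elbow": ("right_shoulder", "right_wrist"),
    "left_hip": ("trunk", "left_knee"),
    "right_hip": ("trunk", "right_knee"),
    "left_knee": ("left_hip", "left_ankle"),
    "right_knee": ("right_hip", "right_ankle"),
}


def _fill_degenerate(angles: np.ndarray, ok: np.ndarray, joint: str) -> np.ndarray:
    """Carry the previous valid angle over frames with zero-length rays."""
    if ok.all():
        return angles
    if not ok.any():
        raise ValueError(f"joint angle {joint}: all frames degenerate")
    idx = np.where(ok, np.arange(len(ok)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.flatnonzero(ok)[0]
    idx[idx < 0] = first  # leading degenerate frames take the first valid angle
    return angles[idx]


def joint_angles(clip: Clip, joint: str) -> np.ndarray:
    """Per-frame interior angle at ``joint`` in degrees, range [0, 180].

    Shoulder and hip angles are measured between the limb's proximal segment
    and the caudal trunk direction; elbow and knee angles between the two
    adjoining limb segments (180 deg = fully extended).
    """
    ref_a, ref_b = _ANGLE_DEFS[joint]
    xy = clip.xy
    vtx = xy[:, KEYPOINT_INDEX[joint]]
    if ref_a == "trunk":
        sm = 0.5 * (xy[:, KEYPOINT_INDEX["left_shoulder"]] + xy[:, KEYPOINT_INDEX["right_shoulder"]])
        hm = 0.5 * (xy[:, KEYPOINT_INDEX["left_hip"]] + xy[:, KEYPOINT_INDEX["right_hip"]])
        ray_a = hm - sm
    else:
        ray_a = xy[:, KEYPOINT_INDEX[ref_a]] - vtx
    ray_b = xy[:, KEYPOINT_INDEX[ref_b]] - vtx
    na = np.linalg.norm(ray_a, axis=-1)
    nb = np.linalg.norm(ray_b, axis=-1)
    ok = (na > 0) & (nb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("td,td->t", ray_a, ray_b) / (na * nb)
    angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return _fill_degenerate(angles, ok, joint)


def _segment_orientation(clip: Clip, joint: str) -> np.ndarray:
    """Unwrapped orientation angle (degrees) of the segment ending at ``joint``."""
    parent = SEGMENT_PARENT[joint]
    d = clip.xy[:, KEYPOINT_INDEX[joint]] - clip.xy[:, KEYPOINT_INDEX[parent]]
    theta = np.arctan2(d[:, 1], d[:, 0])
    return np.degrees(np.unwrap(theta))


# ---------------------------------------------------------------------------
# Windowed correlation and entropy
# ---------------------------------------------------------------------------


def windowed_correlation(
    a: np.ndarray,
    b: np.ndarray,
    width: int = DEFAULT_CORRELATION_WINDOW,
    atol: float = 1e-8,
) -> float:
    """Mean Pearson correlation over all sliding windows of ``width`` samples.

    Windows in which either series is constant are skipped; if every window
    is skipped the correlation is reported as 0.  ``atol`` is the absolute
    standard-deviation floor below which a window counts as constant: the
    anchor joints (shoulders, hips) are static in the normalized frame up to
    floating-point residue, and correlations of that residue are meaningless.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if width < 2 or width > len(a):
        raise ValueError(f"window width {width} invalid for series of length {len(a)}")
    wa = np.lib.stride_tricks.sliding_window_view(a, width)
    wb = np.lib.stride_tricks.sliding_window_view(b, width)
    ma = wa.mean(axis=1, keepdims=True)
    mb = wb.mean(axis=1, keepdims=True)
    da = wa - ma
    db = wb - mb
    sa = np.sqrt((da**2).sum(axis=1))
    sb = np.sqrt((db**2).sum(axis=1))
    floor = atol * np.sqrt(width)
    tol_a = np.maximum(floor, _CONST_TOL * np.abs(ma[:, 0]))
    tol_b = np.maximum(floor, _CONST_TOL * np.abs(mb[:, 0]))
    keep = (sa > tol_a) & (sb > tol_b)
    if not keep.any():
        return 0.0
    r = (da[keep] * db[keep]).sum(axis=1) / (sa[keep] * sb[keep])
    return float(np.clip(r, -1.0, 1.0).mean())


def histogram_entropy(series: np.ndarray, bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Shannon entropy (nats) of the series over equal-width bins of its range.

    A constant series occupies one bin and has entropy 0.  Values lie in
    [0, ln(bins)].
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("entropy of empty series")
    lo, hi = series.min(), series.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(series, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / series.size
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Full catalog
# ---------------------------------------------------------------------------


def _mag_stats(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.max())


def extract_features(
    clip: Clip,
    entropy_bins: int = DEFAULT_ENTROPY_BINS,
    correlation_window: int = DEFAULT_CORRELATION_WINDOW,
) -> FeatureVector:
    """Compute the 227-feature vector for one normalized clip.

    Deterministic given the clip; every feature is finite.
    """
    fps = clip.fps
    v_all = _all_velocities(clip)  # (T, 17, 2)
    speed_all = np.linalg.norm(v_all, axis=-1)  # (T, 17)
    acc_all = np.linalg.norm(_series_derivative(v_all, fps), axis=-1)

    values: list[float] = []

    d_speed = speed_all[:, DISTAL_INDICES]  # (T, 8)
    d_acc = acc_all[:, DISTAL_INDICES]
    for k in range(len(DISTAL_JOINTS)):  # blocks 1-2
        values += _mag_stats(d_speed[:, k])
    for k in range(len(DISTAL_JOINTS)):
        values += _mag_stats(d_acc[:, k])
    for k in range(len(DISTAL_JOINTS)):  # blocks 3-4
        values.append(histogram_entropy(d_speed[:, k], entropy_bins))
    for k in range(len(DISTAL_JOINTS)):
        values.append(histogram_entropy(d_acc[:, k], entropy_bins))

    # blocks 5-6: orientation kinematics of the segment ending at each joint
    seg_angvel = {}
    for j in DISTAL_JOINTS:
        theta = _segment_orientation(clip, j)
        seg_angvel[j] = _series_derivative(theta, fps)
    for j in DISTAL_JOINTS:
        values += _mag_stats(np.abs(seg_angvel[j]))
    for j in DISTAL_JOINTS:
        values += _mag_stats(np.abs(_series_derivative(seg_angvel[j], fps)))

    # blocks 7-9: interior joint angles and their derivatives
    ang = {j: joint_angles(clip, j) for j in ANGLE_JOINTS}
    for j in ANGLE_JOINTS:
        a = ang[j]
        values += [
            float(a.mean()),
            float(a.max()),
            float(a.min()),
            float(a.std()),
            float(a.max() - a.min()),
        ]
    angvel = {j: _series_derivative(ang[j], fps) for j in ANGLE_JOINTS}
    for j in ANGLE_JOINTS:
        w = np.abs(angvel[j])
        values += [float(w.mean()), float(w.max()), float(w.std())]
    for j in ANGLE_JOINTS:
        al = np.abs(_series_derivative(angvel[j], fps))
        values += [float(al.mean()), float(al.max()), float(al.std())]

    # block 10: windowed correlations between angle-joint speed/accel series
    joint_speed = {j: speed_all[:, KEYPOINT_INDEX[j]] for j in ANGLE_JOINTS}
    joint_acc = {j: acc_all[:, KEYPOINT_INDEX[j]] for j in ANGLE_JOINTS}
    for a, b in combinations(ANGLE_JOINTS, 2):
        values.append(windowed_correlation(joint_speed[a], joint_speed[b], correlation_window))
    for a, b in combinations(ANGLE_JOINTS, 2):
        values.append(windowed_correlation(joint_acc[a], joint_acc[b], correlation_window))

    # block 11: whole-body summaries over all 17 keypoints
    values.append(float(speed_all.mean()))
    values.append(float(acc_all.mean()))
    values.append(histogram_entropy(speed_all.ravel(), entropy_bins))

    vec = np.asarray(values)
    if not np.isfinite(vec).all():
        raise ValueError(f"non-finite feature for clip {clip.clip_id}")
    return FeatureVector(values=vec, clip_ref=clip.clip_id, label=clip.label)


def catalog_schema() -> dict:
    """Machine-readable description of the 227-feature catalog."""
    blocks = [
        ("distal_speed_stats", 16), ("distal_accel_stats", 16),
        ("distal_speed_entropy", 8), ("distal_accel_entropy", 8),
        ("distal_segment_angular_velocity", 16), ("distal_segment_angular_acceleration", 16),
        ("joint_angle_stats", 40), ("joint_angular_velocity_stats", 24),
        ("joint_angular_acceleration_stats", 24), ("windowed_correlations", 56),
        ("whole_body_summaries", 3),
    ]
    return {
        "n_features": N_FEATURES,
        "blocks": [{"name": n, "count": c} for n, c in blocks],
        "distal_joints": list(DISTAL_JOINTS),
        "angle_joints": list(ANGLE_JOINTS),
        "entropy_bins": DEFAULT_ENTROPY_BINS,
        "correlation_window": DEFAULT_CORRELATION_WINDOW,
        "features": list(FEATURE_NAMES),
    }


def features_table(clips: list[Clip], **kwargs) -> pd.DataFrame:
    """Feature table: one row per clip, 227 feature columns + metadata.

    Columns: subject_id, clip_id, label, then the catalog in fixed order.
    """
    rows = []
    for clip in clips:
        fv = extract_features(clip, **kwargs)
        row = {"subject_id": clip.subject_id, "clip_id": clip.clip_id, "label": fv.label}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "clip_id", "label", *FEATURE_NAMES])
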