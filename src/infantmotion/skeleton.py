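"""Skeletal sequence container, COCO-style keypoint I/O, confidence gating
and gap interpolation.

A sequence holds per-frame 2-D positions for the 17 COCO keypoints together
with detector confidences and a visibility mask.  Coordinates follow the
image convention: 0-based pixels, origin top-left, y increasing downward.
A *missing* keypoint (``visible == False``) has undefined position and zero
confidence; downstream stages must interpolate before computing kinematics.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "COCO_KEYPOINTS",
    "N_KEYPOINTS",
    "KEYPOINT_INDEX",
    "SkeletonSequence",
    "SchemaError",
    "UnrecoverableTrackError",
    "read_sequence",
    "write_sequence",
    "read_sequence_csv",
    "write_sequence_csv",
    "filter_low_confidence",
    "interpolate_missing",
    "sequences_equal",
]

# Fixed COCO keypoint order; all arrays in this package index joints this way.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)
N_KEYPOINTS = len(COCO_KEYPOINTS)
KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

PIXELS = "pixels"
TRUNK_LENGTHS = "trunk_lengths"

DEFAULT_CONFIDENCE_THRESHOLD = 0.5


class SchemaError(ValueError):
    """A file or array does not conform to the 17-keypoint sequence schema."""


class UnrecoverableTrackError(ValueError):
    """A keypoint track is visible in zero frames and cannot be interpolated."""


@dataclass
class SkeletonSequence:
    """An ordered per-frame 17-keypoint skeleton track for one infant.

    Attributes
    ----------
    xy : ndarray, shape (T, 17, 2)
        Keypoint positions.  Positions of missing keypoints are undefined
        (stored as 0) and must not be read before interpolation.
    confidence : ndarray, shape (T, 17)
        Detector scores in [0, 1]; 0 for missing keypoints.
    visible : ndarray of bool, shape (T, 17)
        Visibility mask; plays the role of the v_i indicator in keypoint
        evaluation.
    fps : float
        Frames per second (nominally 15).
    units : str
        ``"pixels"`` for raw detector output, ``"trunk_lengths"`` after
        normalization.
    subject_id : str
        Opaque identifier.
    label : str or None
        ``"typical"`` or ``"delayed"`` when known.
    """

    xy: np.ndarray
    confidence: np.ndarray
    visible: np.ndarray
    fps: float
    units: str = PIXELS
    subject_id: str = "unknown"
    label: str | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise SchemaError(
                f"xy must have shape (T, {N_KEYPOINTS}, 2), got {self.xy.shape}"
            )
        if self.confidence.shape != self.xy.shape[:2]:
            raise SchemaError("confidence shape does not match xy")
        if self.visible.shape != self.xy.shape[:2]:
            raise SchemaError("visible shape does not match xy")
        if not self.fps > 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        if self.units not in (PIXELS, TRUNK_LENGTHS):
            raise SchemaError(f"unknown units {self.units!r}")
        if self.label not in (None, "typical", "delayed"):
            raise SchemaError(f"unknown label {self.label!r}")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def duration(self) -> float:
        """Sequence duration in seconds."""
        return self.n_frames / self.fps

    def copy(self) -> "SkeletonSequence":
        return replace(
            self,
            xy=self.xy.copy(),
            confidence=self.confidence.copy(),
            visible=self.visible.copy(),
        )

    def is_complete(self) -> bool:
        """True when no keypoint is missing in any frame."""
        return bool(self.visible.all())


def sequences_equal(a: SkeletonSequence, b: SkeletonSequence) -> bool:
    """Exact equality ignoring the undefined positions of missing keypoints."""
    if (a.fps, a.units, a.subject_id, a.label) != (b.fps, b.units, b.subject_id, b.label):
        return False
    if a.xy.shape != b.xy.shape or not np.array_equal(a.visible, b.visible):
        return False
    if not np.array_equal(a.confidence, b.confidence):
        return False
    m = a.visible
    return bool(np.array_equal(a.xy[m], b.xy[m]))


# ---------------------------------------------------------------------------
# COCO-style keypoint JSON
#
# One record per frame: {"frame_index": int, "keypoints": [x0, y0, c0, ...]}
# (17 x 3 flat floats, COCO order), wrapped with sequence-level metadata.
# A keypoint with confidence 0 is missing; its coordinates are written as 0.
# ---------------------------------------------------------------------------


def _canonical(seq: SkeletonSequence) -> SkeletonSequence:
    """Zero out undefined fields of missing keypoints for stable round-trips."""
    out = seq.copy()
    miss = ~out.visible
    out.xy[miss] = 0.0
    out.confidence[miss] = 0.0
    return out


def write_sequence(seq: SkeletonSequence, path: str | Path) -> None:
    """Write a sequence as COCO-style keypoint JSON."""
    seq = _canonical(seq)
    frames = []
    for t in range(seq.n_frames):
        flat = np.concatenate(
            [seq.xy[t], seq.confidence[t][:, None]], axis=1
        ).ravel()
        frames.append({"frame_index": t, "keypoints": [float(v) for v in flat]})
    doc = {
        "format": "infantmotion-keypoint-sequence-v1",
        "fps": seq.fps,
        "units": seq.units,
        "subject_id": seq.subject_id,
        "label": seq.label,
        "keypoint_names": list(COCO_KEYPOINTS),
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))


def read_sequence(path: str | Path) -> SkeletonSequence:
    """Read a COCO-style keypoint JSON sequence.

    Raises
    ------
    SchemaError
        On malformed records, naming the offending frame.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise SchemaError(f"{path}: missing 'frames' array")
    records = doc["frames"]
    xy = np.zeros((len(records), N_KEYPOINTS, 2))
    conf = np.zeros((len(records), N_KEYPOINTS))
    for t, rec in enumerate(records):
        idx = rec.get("frame_index")
        if idx != t:
            raise SchemaError(
                f"{path}: frame {t}: frame_index {idx!r} not strictly increasing from 0"
            )
        kps = rec.get("keypoints")
        if not isinstance(kps, list) or len(kps) != N_KEYPOINTS * 3:
            n = len(kps) // 3 if isinstance(kps, list) else "?"
            raise SchemaError(
                f"{path}: frame {t}: expected {N_KEYPOINTS} keypoints, got {n}"
            )
        arr = np.asarray(kps, dtype=float).reshape(N_KEYPOINTS, 3)
        xy[t] = arr[:, :2]
        conf[t] = arr[:, 2]
    if np.any(conf < 0) or np.any(conf > 1):
        raise SchemaError(f"{path}: confidence outside [0, 1]")
    return SkeletonSequence(
        xy=xy,
        confidence=conf,
        visible=conf > 0,
        fps=float(doc.get("fps", 15.0)),
        units=doc.get("units", PIXELS),
        subject_id=str(doc.get("subject_id", "unknown")),
        label=doc.get("label"),
    )


# ---------------------------------------------------------------------------
# CSV export: one row per frame, columns kp00_x, kp00_y, kp00_c, ...
# Sequence metadata is carried in '#key=value' comment lines at the top.
# ---------------------------------------------------------------------------


def write_sequence_csv(seq: SkeletonSequence, path: str | Path) -> None:
    seq = _canonical(seq)
    buf = io.StringIO()
    buf.write(f"#fps={seq.fps}\n#units={seq.units}\n#subject_id={seq.subject_id}\n")
    if seq.label is not None:
        buf.write(f"#label={seq.label}\n")
    writer = csv.writer(buf)
    header = ["frame_index"]
    for k in range(N_KEYPOINTS):
        header += [f"kp{k:02d}_x", f"kp{k:02d}_y", f"kp{k:02d}_c"]
    writer.writerow(header)
    for t in range(seq.n_frames):
        row: list[object] = [t]
        for k in range(N_KEYPOINTS):
            row += [
                repr(float(seq.xy[t, k, 0])),
                repr(float(seq.xy[t, k, 1])),
                repr(float(seq.confidence[t, k])),
            ]
        writer.writerow(row)
    Path(path).write_text(buf.getvalue())


def read_sequence_csv(path: str | Path) -> SkeletonSequence:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            else:
                rows.append(line)
    reader = csv.reader(rows)
    header = next(reader, None)
    expected_cols = 1 + 3 * N_KEYPOINTS
    if header is None or len(header) != expected_cols:
        raise SchemaError(f"{path}: expected {expected_cols} columns")
    xy_list, conf_list = [], []
    for t, row in enumerate(reader):
        if len(row) != expected_cols:
            raise SchemaError(f"{path}: frame {t}: wrong column count")
        vals = np.asarray(row[1:], dtype=float).reshape(N_KEYPOINTS, 3)
        xy_list.append(vals[:, :2])
        conf_list.append(vals[:, 2])
    xy = np.asarray(xy_list)
    conf = np.asarray(conf_list)
    return SkeletonSequence(
        xy=xy,
        confidence=conf,
        visible=conf > 0,
        fps=float(meta.get("fps", 15.0)),
        units=meta.get("units", PIXELS),
        subject_id=meta.get("subject_id", "unknown"),
        label=meta.get("label"),
    )


# ---------------------------------------------------------------------------
# Confidence gating and gap interpolation
# ---------------------------------------------------------------------------


def filter_low_confidence(
    seq: SkeletonSequence, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> SkeletonSequence:
    """Mark keypoints with confidence strictly below ``threshold`` as missing.

    Keypoints at exactly the threshold are kept (strict ``<``).  Already
    missing keypoints stay missing.  Idempotent for a fixed threshold.
    """
    out = seq.copy()
    drop = out.visible & (out.confidence < threshold)
    out.visible[drop] = False
    out.confidence[drop] = 0.0
    out.xy[drop] = 0.0
    return out


def interpolate_missing(
    seq: SkeletonSequence, fill_confidence: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> SkeletonSequence:
    """Fill missing keypoints by per-track linear interpolation.

    Interior gaps are interpolated coordinate-wise between the nearest
    visible neighbours; leading/trailing gaps take the nearest visible value
    (no extrapolation).  Filled points become visible with confidence
    ``fill_confidence``.  A sequence that is already complete is returned
    unchanged (bit-identical arrays).

    Raises
    ------
    UnrecoverableTrackError
        If any keypoint track is visible in zero frames.
    """
    never = ~seq.visible.any(axis=0)
    if never.any():
        names = [COCO_KEYPOINTS[i] for i in np.flatnonzero(never)]
        raise UnrecoverableTrackError(
            f"subject {seq.subject_id!r}: keypoint track(s) never visible: "
            + ", ".join(names)
        )
    if seq.is_complete():
        return seq.copy()
    out = seq.copy()
    t_all = np.arange(seq.n_frames)
    for k in range(N_KEYPOINTS):
        vis = seq.visible[:, k]
        if vis.all():
            continue
        t_vis = t_all[vis]
        for d in range(2):
            # np.interp clamps outside [t_vis[0], t_vis[-1]]: nearest-value
            # extension at the ends, linear inside.
            out.xy[:, k, d] = np.interp(t_all, t_vis, seq.xy[vis, k, d])
        out.confidence[~vis, k] = fill_confidence
        out.visible[:, k] = True
    return out
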