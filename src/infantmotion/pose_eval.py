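"""Object keypoint similarity (OKS) and threshold-swept mAP/mAR.

OKS scores a predicted skeleton against its ground truth as the
visibility-masked mean of Gaussian keypoint agreements::

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

where d_i is the Euclidean pixel distance for keypoint i, s the object
scale, k_i a per-keypoint tolerance constant, and v_i the ground-truth
visibility.  mAP/mAR average the per-threshold precision/recall over the
OKS thresholds 0.50, 0.55, ..., 0.95.  In the single-infant, one-prediction-
per-image regime implemented here, matching is 1:1 and precision equals
recall at every threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton import N_KEYPOINTS

__all__ = [
    "COCO_SIGMAS",
    "DEFAULT_KAPPAS",
    "DEFAULT_THRESHOLDS",
    "KeypointEvalCase",
    "ThresholdSweep",
    "UnscorableCaseError",
    "oks",
    "sweep_ap_ar",
    "map_mar",
    "object_scale_from_area",
    "read_eval_cases",
    "evaluate_files",
]

# Canonical MS-COCO per-keypoint falloff constants (sigmas); the OKS
# tolerance is k_i = 2 * sigma_i by the COCO evaluation convention.
COCO_SIGMAS = np.array(
    [0.026, 0.025, 0.025, 0.035, 0.035, 0.079, 0.079, 0.072, 0.072,
     0.062, 0.062, 0.107, 0.107, 0.087, 0.087, 0.089, 0.089]
)
DEFAULT_KAPPAS = 2.0 * COCO_SIGMAS

DEFAULT_THRESHOLDS = np.round(np.arange(0.50, 0.951, 0.05), 2)


class UnscorableCaseError(ValueError):
    """No visible ground-truth keypoint: OKS is undefined."""


def object_scale_from_area(area: float, convention: str = "sqrt_area") -> float:
    """Object scale s from an annotated bounding-box area.

    ``"sqrt_area"`` (the standard COCO convention) takes s = sqrt(area);
    ``"area"`` uses the area directly, the literal reading of "s is the
    pixel area".  Either way the OKS formula divides by 2 s^2 k^2.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if convention == "sqrt_area":
        return float(np.sqrt(area))
    if convention == "area":
        return float(area)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class KeypointEvalCase:
    """Predicted vs ground-truth keypoints for one image."""

    predicted: np.ndarray  # (17, 2) pixels
    ground_truth: np.ndarray  # (17, 2) pixels
    visibility: np.ndarray  # (17,) ground-truth v_i; scored iff v_i > 0
    object_scale: float  # s, pixels
    kappas: np.ndarray = field(default_factory=lambda: DEFAULT_KAPPAS.copy())
    case_id: str = ""

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.ground_truth = np.asarray(self.ground_truth, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=float)
        self.kappas = np.asarray(self.kappas, dtype=float)
        for name, arr, shape in (
            ("predicted", self.predicted, (N_KEYPOINTS, 2)),
            ("ground_truth", self.ground_truth, (N_KEYPOINTS, 2)),
            ("visibility", self.visibility, (N_KEYPOINTS,)),
            ("kappas", self.kappas, (N_KEYPOINTS,)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if np.any(self.kappas <= 0):
            raise ValueError("kappas must be positive")


def oks(case: KeypointEvalCase) -> float:
    """Object keypoint similarity in [0, 1] for one case."""
    if case.object_scale <= 0:
        raise ValueError(f"object_scale must be positive, got {case.object_scale}")
    mask = case.visibility > 0
    if not mask.any():
        raise UnscorableCaseError(f"case {case.case_id!r}: no visible keypoint")
    d2 = ((case.predicted[mask] - case.ground_truth[mask]) ** 2).sum(axis=1)
    terms = np.exp(-d2 / (2.0 * case.object_scale**2 * case.kappas[mask] ** 2))
    return float(terms.mean())


@dataclass
class ThresholdSweep:
    """Per-threshold precision/recall over an OKS threshold grid."""

    thresholds: np.ndarray = field(default_factory=lambda: DEFAULT_THRESHOLDS.copy())
    ap: np.ndarray | None = None
    ar: np.ndarray | None = None
    oks_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or len(self.thresholds) == 0:
            raise ValueError("thresholds must be a non-empty 1-D array")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any((self.thresholds <= 0) | (self.thresholds > 1)):
            raise ValueError("thresholds must lie in (0, 1]")


def sweep_ap_ar(
    cases: list[KeypointEvalCase], sweep: ThresholdSweep | None = None
) -> ThresholdSweep:
    """Fill AP_i/AR_i: the fraction of cases with OKS >= each threshold.

    With one prediction per ground-truth instance, every case is either a
    true positive (OKS >= t) or both a false positive and a false negative,
    so AP_i = AR_i = TP / total.
    """
    if sweep is None:
        sweep = ThresholdSweep()
    if not cases:
        raise UnscorableCaseError("no scorable cases")
    scores = np.array([oks(c) for c in cases])
    tp = (scores[None, :] >= sweep.thresholds[:, None]).mean(axis=1)
    sweep.oks_scores = scores
    sweep.ap = tp.copy()
    sweep.ar = tp.copy()
    return sweep


def map_mar(sweep: ThresholdSweep) -> tuple[float, float]:
    """Arithmetic means of AP_i and AR_i over the threshold grid."""
    if sweep.ap is None or sweep.ar is None:
        raise ValueError("sweep not filled; run sweep_ap_ar first")
    return float(sweep.ap.mean()), float(sweep.ar.mean())


# ---------------------------------------------------------------------------
# COCO keypoint-results file I/O
# ---------------------------------------------------------------------------


def _index_records(doc) -> dict:
    records = doc["annotations"] if isinstance(doc, dict) and "annotations" in doc else doc
    out = {}
    for rec in records:
        key = rec.get("image_id", rec.get("id"))
        out[key] = rec
    return out


def read_eval_cases(
    pred_path: str | Path,
    gt_path: str | Path,
    kappas: np.ndarray | None = None,
    scale_convention: str = "sqrt_area",
) -> list[KeypointEvalCase]:
    """Pair COCO keypoint-results JSON files into evaluation cases.

    Records are matched on ``image_id``.  Ground-truth records carry
    ``keypoints`` as 17 x 3 flat (x, y, v) and a bounding-box ``area`` (or
    an explicit ``scale``); prediction records carry 17 x 3 (x, y, score).
    """
    preds = _index_records(json.loads(Path(pred_path).read_text()))
    gts = _index_records(json.loads(Path(gt_path).read_text()))
    if kappas is None:
        kappas = DEFAULT_KAPPAS
    cases = []
    for key in sorted(gts):
        if key not in preds:
            raise ValueError(f"no prediction for image_id {key!r}")
        g = np.asarray(gts[key]["keypoints"], dtype=float).reshape(N_KEYPOINTS, 3)
        p = np.asarray(preds[key]["keypoints"], dtype=float).reshape(N_KEYPOINTS, 3)
        if "scale" in gts[key]:
            s = float(gts[key]["scale"])
        else:
            s = object_scale_from_area(float(gts[key]["area"]), scale_convention)
        cases.append(
            KeypointEvalCase(
                predicted=p[:, :2],
                ground_truth=g[:, :2],
                visibility=g[:, 2],
                object_scale=s,
                kappas=np.asarray(kappas, dtype=float),
                case_id=str(key),
            )
        )
    return cases


def evaluate_files(
    pred_path: str | Path, gt_path: str | Path, **kwargs
) -> dict:
    """OKS per case plus the mAP/mAR summary for paired result files."""
    cases = read_eval_cases(pred_path, gt_path, **kwargs)
    sweep = sweep_ap_ar(cases)
    m_ap, m_ar = map_mar(sweep)
    return {
        "per_case_oks": {c.case_id: float(s) for c, s in zip(cases, sweep.oks_scores)},
        "thresholds": [float(t) for t in sweep.thresholds],
        "ap": [float(a) for a in sweep.ap],
        "ar": [float(a) for a in sweep.ar],
        "mAP": m_ap,
        "mAR": m_ar,
    }
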