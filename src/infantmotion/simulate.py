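"""Synthetic supine infant motion with a controllable developmental-delay effect.

The simulator drives a planar kinematic chain (shoulder -> elbow -> wrist,
hip -> knee -> ankle, both sides) with seeded sums of sinusoids on the
segment orientation angles, viewed from directly above.  The delay class
attenuates limb oscillation amplitude and frequency (a hypokinesia proxy)
and adds left-right coupling; the direction of these effects is a modeling
choice of this package, not a clinical claim.  A per-subject camera
transform (rotation, translation, pixel scale), Gaussian keypoint jitter,
dropout and low-confidence assignment emulate the imperfections of real
pose-estimator output, so every pipeline stage can be exercised without
videos.

The base oscillation is vigorous enough that even delay-attenuated motion
clears the 0.9 trunk-length/s activity gate: the simulator emulates clips
that have already passed segment selection, mirroring the modeling cohort
it stands in for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import COCO_KEYPOINTS, KEYPOINT_INDEX, N_KEYPOINTS, SkeletonSequence

__all__ = ["Oscillator", "EffectParams", "SimulationParams", "simulate_sequence", "simulate_cohort"]


@dataclass
class Oscillator:
    """One segment's angular oscillation: amplitude (rad) and frequency (Hz)."""

    amplitude: float
    frequency: float


@dataclass
class EffectParams:
    """Delay-class modifiers applied to every limb oscillator."""

    amplitude_multiplier: float = 0.4
    frequency_multiplier: float = 0.6
    coupling: float = 0.5  # blend weight toward the left-right common drive


@dataclass
class SimulationParams:
    """Generator settings; the seed fully determines the output."""

    fps: float = 15.0
    duration: float = 16.0  # seconds; one full 15 s clip per subject
    # Base oscillators per joint type (left/right share settings, not phases).
    shoulder_osc: Oscillator = field(default_factory=lambda: Oscillator(1.8, 1.8))
    elbow_osc: Oscillator = field(default_factory=lambda: Oscillator(2.0, 2.3))
    hip_osc: Oscillator = field(default_factory=lambda: Oscillator(1.6, 1.6))
    knee_osc: Oscillator = field(default_factory=lambda: Oscillator(1.8, 2.1))
    harmonic_weight: float = 0.4  # second harmonic for movement complexity
    harmonic_ratio: float = 1.7
    effect: EffectParams = field(default_factory=EffectParams)
    subject_jitter: float = 0.12  # log-sd of per-subject amp/freq variation
    drift_rotation: float = 0.10  # rad, slow whole-body wobble
    drift_translation: float = 0.05  # trunk lengths
    noise_sd: float = 0.01  # trunk lengths, keypoint jitter
    missing_prob: float = 0.02
    low_conf_prob: float = 0.03
    camera_scale_range: tuple[float, float] = (120.0, 250.0)  # px per trunk length
    camera_translation_range: tuple[float, float] = (200.0, 800.0)  # px
    seed: int = 0


# Canonical supine pose, trunk length 1, shoulder midpoint at origin,
# trunk along +y (image convention: head toward -y).  COCO "left" keypoints
# sit at +x; the camera roll is randomized anyway.
_BASE_POSE = {
    "nose": (0.0, -0.55),
    "left_eye": (0.08, -0.63),
    "right_eye": (-0.08, -0.63),
    "left_ear": (0.16, -0.57),
    "right_ear": (-0.16, -0.57),
    "left_shoulder": (0.35, 0.0),
    "right_shoulder": (-0.35, 0.0),
    "left_hip": (0.22, 1.0),
    "right_hip": (-0.22, 1.0),
}

_L_UPPER_ARM = 0.45
_L_FOREARM = 0.40
_L_THIGH = 0.50
_L_SHANK = 0.45

# Resting segment orientations (degrees, atan2 convention) for the left
# side; the right side mirrors across the trunk axis.
_BASE_ANGLES = {"upper_arm": 55.0, "elbow_bend": -50.0, "thigh": 70.0, "knee_bend": -40.0}


def _dir(theta: np.ndarray) -> np.ndarray:
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def _oscillation(
    t: np.ndarray, osc: Oscillator, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Seeded sum-of-sinusoids angular excursion (radians) over time."""
    amp = osc.amplitude * float(np.exp(rng.normal(0.0, params.subject_jitter)))
    freq = osc.frequency * float(np.exp(rng.normal(0.0, params.subject_jitter)))
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    out = amp * np.sin(2.0 * np.pi * freq * t + phase1)
    if params.harmonic_weight:
        out = out + amp * params.harmonic_weight * np.sin(
            2.0 * np.pi * freq * params.harmonic_ratio * t + phase2
        )
    return out


def simulate_sequence(
    params: SimulationParams,
    label: str = "typical",
    subject_id: str = "sim000",
    rng: np.random.Generator | None = None,
) -> SkeletonSequence:
    """Generate one labeled skeletal sequence in pixel units.

    A ``delayed`` label applies the effect multipliers to every limb
    oscillator and blends the left/right drives by the coupling weight.
    """
    if label not in ("typical", "delayed"):
        raise ValueError(f"unknown label {label!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fps))
    t = np.arange(n) / params.fps

    if label == "delayed":
        eff = params.effect
        scale_osc = lambda o: Oscillator(  # noqa: E731
            o.amplitude * eff.amplitude_multiplier, o.frequency * eff.frequency_multiplier
        )
        coupling = eff.coupling
    else:
        scale_osc = lambda o: o  # noqa: E731
        coupling = 0.0

    # Angular excursions per side and joint type, with optional L/R coupling.
    exc: dict[tuple[str, str], np.ndarray] = {}
    for kind, osc in (
        ("upper_arm", params.shoulder_osc),
        ("elbow_bend", params.elbow_osc),
        ("thigh", params.hip_osc),
        ("knee_bend", params.knee_osc),
    ):
        o = scale_osc(osc)
        left = _oscillation(t, o, params, rng)
        right = _oscillation(t, o, params, rng)
        if coupling > 0.0:
            common = 0.5 * (left + right)
            left = (1.0 - coupling) * left + coupling * common
            right = (1.0 - coupling) * right + coupling * common
        exc[("left", kind)] = left
        exc[("right", kind)] = right

    xy = np.zeros((n, N_KEYPOINTS, 2))
    for name, pos in _BASE_POSE.items():
        xy[:, KEYPOINT_INDEX[name]] = pos

    for side, sign in (("left", 1.0), ("right", -1.0)):
        sh = xy[:, KEYPOINT_INDEX[f"{side}_shoulder"]]
        hp = xy[:, KEYPOINT_INDEX[f"{side}_hip"]]
        # Orientation angles: mirror the resting pose across the trunk axis.
        th_ua = np.radians(_BASE_ANGLES["upper_arm"] if side == "left" else 180.0 - _BASE_ANGLES["upper_arm"])
        th_th = np.radians(_BASE_ANGLES["thigh"] if side == "left" else 180.0 - _BASE_ANGLES["thigh"])
        bend_el = sign * np.radians(_BASE_ANGLES["elbow_bend"])
        bend_kn = sign * np.radians(_BASE_ANGLES["knee_bend"])

        theta_ua = th_ua + sign * exc[(side, "upper_arm")]
        theta_fa = theta_ua + bend_el + sign * exc[(side, "elbow_bend")]
        theta_th = th_th + sign * exc[(side, "thigh")]
        theta_sh = theta_th + bend_kn + sign * exc[(side, "knee_bend")]

        elbow = sh + _L_UPPER_ARM * _dir(theta_ua)
        wrist = elbow + _L_FOREARM * _dir(theta_fa)
        knee = hp + _L_THIGH * _dir(theta_th)
        ankle = knee + _L_SHANK * _dir(theta_sh)
        xy[:, KEYPOINT_INDEX[f"{side}_elbow"]] = elbow
        xy[:, KEYPOINT_INDEX[f"{side}_wrist"]] = wrist
        xy[:, KEYPOINT_INDEX[f"{side}_knee"]] = knee
        xy[:, KEYPOINT_INDEX[f"{side}_ankle"]] = ankle

    # Slow rigid whole-body wobble: cancelled by normalization downstream,
    # but exercises the per-frame rotation/translation handling.
    if params.drift_rotation or params.drift_translation:
        ph = rng.uniform(0.0, 2.0 * np.pi, size=3)
        beta = params.drift_rotation * np.sin(2.0 * np.pi * 0.08 * t + ph[0])
        cb, sb = np.cos(beta), np.sin(beta)
        rot = np.stack([np.stack([cb, -sb], -1), np.stack([sb, cb], -1)], -2)
        xy = np.einsum("tij,tkj->tki", rot, xy)
        xy += params.drift_translation * np.stack(
            [np.sin(2.0 * np.pi * 0.06 * t + ph[1]), np.sin(2.0 * np.pi * 0.05 * t + ph[2])],
            axis=-1,
        )[:, None, :]

    # Camera transform: trunk-unit coordinates -> pixels.
    alpha = rng.uniform(0.0, 2.0 * np.pi)
    px_scale = rng.uniform(*params.camera_scale_range)
    trans = rng.uniform(*params.camera_translation_range, size=2)
    ca, sa = np.cos(alpha), np.sin(alpha)
    cam = np.array([[ca, -sa], [sa, ca]])
    xy = xy @ cam.T * px_scale + trans

    if params.noise_sd > 0:
        xy = xy + rng.normal(0.0, params.noise_sd * px_scale, size=xy.shape)

    conf = rng.uniform(0.85, 1.0, size=(n, N_KEYPOINTS))
    low = rng.random((n, N_KEYPOINTS)) < params.low_conf_prob
    conf[low] = rng.uniform(0.05, 0.45, size=int(low.sum()))
    missing = rng.random((n, N_KEYPOINTS)) < params.missing_prob
    conf[missing] = 0.0
    xy[missing] = 0.0

    return SkeletonSequence(
        xy=xy,
        confidence=conf,
        visible=~missing,
        fps=params.fps,
        units="pixels",
        subject_id=subject_id,
        label=label,
    )


def simulate_cohort(
    n_typical: int, n_delayed: int, params: SimulationParams | None = None
) -> list[SkeletonSequence]:
    """Independent labeled sequences for a two-class cohort.

    Each subject gets a child seed spawned from ``params.seed``, its own
    camera, and its own oscillator jitter, so features vary within class.
    """
    if params is None:
        params = SimulationParams()
    seqs = []
    children = np.random.SeedSequence(params.seed).spawn(n_typical + n_delayed)
    for i in range(n_typical + n_delayed):
        label = "typical" if i < n_typical else "delayed"
        rng = np.random.default_rng(children[i])
        seqs.append(
            simulate_sequence(params, label=label, subject_id=f"sim{i:03d}", rng=rng)
        )
    return seqs
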