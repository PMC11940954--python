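"""Kinematic series, joint angles, windowed correlation, entropy, the catalog."""

import numpy as np
import pytest

from infantmotion import (
    FEATURE_NAMES,
    KEYPOINT_INDEX,
    N_FEATURES,
    N_KEYPOINTS,
    acceleration_series,
    extract_features,
    features_table,
    histogram_entropy,
    joint_angles,
    speed_series,
    windowed_correlation,
)
from infantmotion.clips import DISTAL_INDICES
from infantmotion.config import preprocess_sequence
from infantmotion.clips import segment_clips
from infantmotion.simulate import simulate_sequence

from conftest import make_clip


def _clip_with_joint_track(track_xy: np.ndarray, joint: str = "left_wrist"):
    xy = np.zeros((len(track_xy), N_KEYPOINTS, 2))
    xy[:, KEYPOINT_INDEX[joint]] = track_xy
    return make_clip(xy)


class TestSpeedAcceleration:
    def test_static_joint_all_zero(self):
        clip = make_clip(np.zeros((50, N_KEYPOINTS, 2)))
        assert np.all(speed_series(clip, "left_wrist") == 0)
        assert np.all(acceleration_series(clip, "left_wrist") == 0)

    def test_uniform_motion_constant_speed_zero_accel(self):
        track = np.stack([0.02 * np.arange(50), np.zeros(50)], axis=1)
        clip = _clip_with_joint_track(track)
        assert np.allclose(speed_series(clip, "left_wrist"), 0.3)
        assert np.allclose(acceleration_series(clip, "left_wrist"), 0.0)

    def test_reversing_motion_constant_speed(self):
        d = 0.05
        track = np.zeros((40, 2))
        track[:, 0] = np.cumsum(d * (-1.0) ** np.arange(40))
        clip = _clip_with_joint_track(track)
        assert np.allclose(speed_series(clip, "left_wrist"), d * 15.0)

    def test_velocity_step_acceleration(self):
        # at rest, then 0.02 units/frame: one-frame velocity step 0 -> 0.3
        track = np.zeros((40, 2))
        track[20:, 0] = 0.02 * np.arange(20)
        clip = _clip_with_joint_track(track)
        acc = acceleration_series(clip, "left_wrist")
        assert acc.max() == pytest.approx(0.3 * 15.0)  # 4.5


class TestJointAngle:
    def _elbow_clip(self, shoulder, elbow, wrist):
        xy = np.zeros((1, N_KEYPOINTS, 2))
        xy[0, KEYPOINT_INDEX["left_shoulder"]] = shoulder
        xy[0, KEYPOINT_INDEX["left_elbow"]] = elbow
        xy[0, KEYPOINT_INDEX["left_wrist"]] = wrist
        # keep the trunk well-defined for shoulder/hip angle rays
        xy[0, KEYPOINT_INDEX["right_shoulder"]] = (1, -1)
        xy[0, KEYPOINT_INDEX["left_hip"]] = (0, 3)
        xy[0, KEYPOINT_INDEX["right_hip"]] = (1, 3)
        return make_clip(xy)

    def test_collinear_limb_is_180(self):
        clip = self._elbow_clip((0, 0), (1, 0), (2, 0))
        assert joint_angles(clip, "left_elbow")[0] == pytest.approx(180.0)

    def test_perpendicular_rays_is_90(self):
        clip = self._elbow_clip((1, 1), (1, 0), (2, 0))  # to-shoulder +y, to-wrist +x
        assert joint_angles(clip, "left_elbow")[0] == pytest.approx(90.0)

    def test_dot_product_arithmetic(self):
        ell = 0.7
        wrist = (1 + np.cos(np.radians(80)) * ell, np.sin(np.radians(80)) * ell)
        clip = self._elbow_clip((0, 0), (1, 0), wrist)
        assert joint_angles(clip, "left_elbow")[0] == pytest.approx(100.0)

    def test_degenerate_frame_carries_previous_angle(self):
        xy = np.zeros((3, N_KEYPOINTS, 2))
        for t, wrist in enumerate([(2, 0), (1, 0), (1, 1)]):  # frame 1: zero-length ray
            xy[t, KEYPOINT_INDEX["left_shoulder"]] = (0, 0)
            xy[t, KEYPOINT_INDEX["left_elbow"]] = (1, 0)
            xy[t, KEYPOINT_INDEX["left_wrist"]] = wrist
        angles = joint_angles(make_clip(xy), "left_elbow")
        assert angles[1] == angles[0] == pytest.approx(180.0)
        assert angles[2] == pytest.approx(90.0)


class TestWindowedCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(size=60)
        assert windowed_correlation(a, a, 5) == pytest.approx(1.0)

    def test_sign_flip_is_minus_one(self, rng):
        a = rng.normal(size=60)
        assert windowed_correlation(a, -a, 5) == pytest.approx(-1.0)

    def test_matches_bruteforce_window_mean(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = np.array([2.0, 1, 4, 3, 6, 5])
        expected = np.mean(
            [np.corrcoef(a[i : i + 5], b[i : i + 5])[0, 1] for i in range(2)]
        )
        assert windowed_correlation(a, b, 5) == pytest.approx(expected, abs=1e-12)

    def test_full_width_equals_plain_pearson(self, rng):
        a, b = rng.normal(size=(2, 30))
        assert windowed_correlation(a, b, 30) == pytest.approx(
            np.corrcoef(a, b)[0, 1], abs=1e-12
        )

    def test_all_constant_windows_give_zero(self):
        assert windowed_correlation(np.ones(10), np.arange(10.0), 5) == 0.0


class TestHistogramEntropy:
    def test_constant_series_zero(self):
        assert histogram_entropy(np.full(100, 3.7)) == 0.0

    def test_uniform_over_all_bins(self):
        assert histogram_entropy(np.arange(10.0), bins=10) == pytest.approx(np.log(10))

    def test_two_point_uniform(self):
        series = np.array([0.0, 1.0] * 50)
        assert histogram_entropy(series, bins=10) == pytest.approx(np.log(2))

    def test_bounded_by_log_bins(self, rng):
        for _ in range(20):
            s = rng.normal(size=rng.integers(2, 200))
            h = histogram_entropy(s, bins=10)
            assert 0.0 <= h <= np.log(10) + 1e-12


class TestCatalog:
    def test_catalog_has_fixed_names(self):
        assert len(FEATURE_NAMES) == N_FEATURES == 227
        assert len(set(FEATURE_NAMES)) == 227

    def test_simulated_clip_vector_length(self, simulated_clip):
        fv = extract_features(simulated_clip)
        assert fv.values.shape == (227,)
        assert np.isfinite(fv.values).all()

    def test_static_clip_features(self):
        xy = np.zeros((225, N_KEYPOINTS, 2))
        # a plausible static pose with non-degenerate limbs
        pose = {
            "left_shoulder": (0.35, 0), "right_shoulder": (-0.35, 0),
            "left_hip": (0.22, 1), "right_hip": (-0.22, 1),
            "left_elbow": (0.7, 0.3), "right_elbow": (-0.7, 0.3),
            "left_wrist": (0.9, 0.0), "right_wrist": (-0.9, 0.0),
            "left_knee": (0.45, 1.4), "right_knee": (-0.45, 1.4),
            "left_ankle": (0.5, 1.8), "right_ankle": (-0.5, 1.8),
        }
        for name, p in pose.items():
            xy[:, KEYPOINT_INDEX[name]] = p
        fv = extract_features(make_clip(xy)).as_dict()
        for name, value in fv.items():
            if any(s in name for s in ("speed", "accel", "angvel", "angacc", "corr")):
                assert value == 0.0, name
        # angle statistics collapse to the static pose's angle
        assert fv["left_elbow_angle_std"] == pytest.approx(0.0, abs=1e-9)
        assert fv["left_elbow_angle_mean"] == pytest.approx(fv["left_elbow_angle_max"])

    def test_mean_never_exceeds_max(self, simulated_clip):
        fv = extract_features(simulated_clip).as_dict()
        for j in ("left_wrist", "right_ankle", "left_elbow"):
            assert fv[f"{j}_speed_mean"] <= fv[f"{j}_speed_max"]
            assert fv[f"{j}_accel_mean"] <= fv[f"{j}_accel_max"]

    def test_feature_invariance_under_camera_transform(self, noiseless_params, rng):
        seq = simulate_sequence(noiseless_params, label="typical", subject_id="s")
        ref = extract_features(segment_clips(preprocess_sequence(seq))[0]).values
        for _ in range(3):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            moved = seq.copy()
            moved.xy = seq.xy @ rot.T * rng.uniform(0.5, 3.0) + rng.uniform(-500, 500, 2)
            got = extract_features(segment_clips(preprocess_sequence(moved))[0]).values
            assert np.allclose(got, ref, atol=1e-6)

    def test_features_table_layout(self, simulated_clip):
        df = features_table([simulated_clip, simulated_clip])
        assert list(df.columns[:3]) == ["subject_id", "clip_id", "label"]
        assert list(df.columns[3:]) == list(FEATURE_NAMES)
        assert len(df) == 2
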