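"""Normalization chain: centering, smoothing, imputation, mirroring, angles."""

import numpy as np
import pytest

from videogait.io_keypoints import KEYPOINT_INDEX, LEFT_RIGHT_PAIRS, KeypointFrameSeries
from videogait.preprocess import (
    CHANNEL_NAMES,
    build_feature_series,
    center_and_scale,
    detect_direction_and_mirror,
    impute_linear,
    preprocess_series,
    projected_joint_angle,
    projected_knee_angle,
    smooth_gaussian,
)
from tests.conftest import standing_pose_keypoints

RHIP = KEYPOINT_INDEX["RHip"]
RSHO = KEYPOINT_INDEX["RShoulder"]
MIDHIP = KEYPOINT_INDEX["MidHip"]
NOSE = KEYPOINT_INDEX["Nose"]


def test_center_and_scale_unit_example():
    kp = standing_pose_keypoints(1)
    kp[0, NOSE, :2] = (150.0, 200.0)  # hip (100,200), shoulder (100,100)
    norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    assert np.allclose(norm.coords[0, NOSE], (0.5, 0.0))
    assert np.allclose(norm.coords[:, RHIP], 0.0)  # the hip is the origin


def test_center_and_scale_translation_and_scale_invariance():
    kp = standing_pose_keypoints(6)
    base = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    shifted = kp.copy()
    shifted[:, :, 0] += 7.0
    shifted[:, :, 1] -= 3.0
    scaled = kp.copy()
    scaled[:, :, :2] *= 2.5
    for variant in (shifted, scaled):
        norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=variant))
        assert np.allclose(norm.coords, base.coords, equal_nan=True)


def test_center_and_scale_degenerate_frame_marked_missing():
    kp = standing_pose_keypoints(3)
    kp[1, RSHO, :2] = kp[1, RHIP, :2]  # zero hip-shoulder distance
    norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    assert norm.missing[1].all()
    assert not norm.missing[0].any()


def test_smoothing_preserves_constants_and_matches_kernel_oracle():
    kp = standing_pose_keypoints(41)
    norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    const = smooth_gaussian(norm, sigma=1.0)
    assert np.allclose(const.coords, norm.coords, atol=1e-12)

    # unit impulse in one channel vs a directly evaluated discrete kernel
    norm.coords[20, NOSE, 0] += 1.0
    sm = smooth_gaussian(norm, sigma=1.0)
    x = np.arange(-4, 5)
    kernel = np.exp(-0.5 * x**2)
    kernel /= kernel.sum()
    bump = sm.coords[16:25, NOSE, 0] - const.coords[16:25, NOSE, 0]
    assert np.allclose(bump, kernel, atol=1e-9)


def test_smoothing_sigma_zero_is_identity():
    kp = standing_pose_keypoints(10)
    norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    out = smooth_gaussian(norm, sigma=0.0)
    assert np.array_equal(out.coords, norm.coords)


def test_smoothing_excludes_missing_samples():
    kp = standing_pose_keypoints(21)
    series = KeypointFrameSeries(video_id="v", keypoints=kp)
    norm = center_and_scale(series)
    norm.coords[10, NOSE] = np.nan
    norm.missing[10, NOSE] = True
    sm = smooth_gaussian(norm, sigma=1.0)
    # neighbors renormalize over available samples: constants stay constant
    obs = ~sm.missing[:, NOSE]
    assert np.allclose(sm.coords[obs, NOSE, 1], norm.coords[0, NOSE, 1])
    assert np.isnan(sm.coords[10, NOSE]).all()


def test_impute_linear_midpoint_and_edge_hold():
    kp = standing_pose_keypoints(3)
    norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    norm.coords[:, NOSE, 0] = [1.0, np.nan, 3.0]
    norm.coords[:, NOSE, 1] = [np.nan, 5.0, 5.0]
    norm.missing[:, NOSE] = np.isnan(norm.coords[:, NOSE]).any(axis=1)
    out = impute_linear(norm)
    assert np.allclose(out.coords[:, NOSE, 0], [1.0, 2.0, 3.0])
    assert np.allclose(out.coords[:, NOSE, 1], [5.0, 5.0, 5.0])
    assert out.pre_imputation_missing[1, NOSE]


def _piecewise_linear_oracle(t, obs_idx, obs_val):
    """Brute-force linear interpolation with edge-hold."""
    out = np.empty(len(t))
    for i, ti in enumerate(t):
        if ti <= obs_idx[0]:
            out[i] = obs_val[0]
        elif ti >= obs_idx[-1]:
            out[i] = obs_val[-1]
        else:
            j = np.searchsorted(obs_idx, ti)
            lo, hi = obs_idx[j - 1], obs_idx[j]
            w = (ti - lo) / (hi - lo)
            out[i] = (1 - w) * obs_val[j - 1] + w * obs_val[j]
    return out


def test_impute_linear_matches_piecewise_oracle_on_noisy_sine():
    rng = np.random.default_rng(3)
    T = 200
    kp = standing_pose_keypoints(T)
    norm = center_and_scale(KeypointFrameSeries(video_id="v", keypoints=kp))
    signal = np.sin(np.linspace(0, 6 * np.pi, T))
    gone = rng.random(T) < 0.2
    values = np.where(gone, np.nan, signal)
    norm.coords[:, NOSE, 0] = values
    norm.missing[:, NOSE] = gone
    out = impute_linear(norm)
    obs = np.flatnonzero(~gone)
    oracle = _piecewise_linear_oracle(np.arange(T), obs, signal[obs])
    assert np.allclose(out.coords[:, NOSE, 0], oracle, atol=1e-12)


def _walking_keypoints(path_x):
    """A rigid standing pose translated along ``path_x`` (pixels)."""
    T = len(path_x)
    kp = standing_pose_keypoints(T)
    kp[:, :, 0] += np.asarray(path_x)[:, None]
    return kp


def test_direction_three_segments_on_back_and_forth_walk():
    path = np.concatenate([
        np.linspace(0, 400, 200),
        np.linspace(400, 100, 150),
        np.linspace(100, 400, 150),
    ])
    series = KeypointFrameSeries(video_id="v", keypoints=_walking_keypoints(path))
    norm = detect_direction_and_mirror(center_and_scale(series))
    dirs = [d for _, _, d in norm.direction_segments]
    assert dirs == ["camera_right", "camera_left", "camera_right"]
    # mid-hip x-velocity sign changes are the oracle for the boundaries
    starts = [s for s, _, _ in norm.direction_segments]
    assert starts[0] == 0
    assert abs(starts[1] - 200) <= 8 and abs(starts[2] - 350) <= 8


def test_direction_stationary_subject_warns_single_segment():
    series = KeypointFrameSeries(video_id="v",
                                 keypoints=standing_pose_keypoints(80))
    norm = detect_direction_and_mirror(center_and_scale(series))
    assert norm.direction_warning
    assert norm.direction_segments == ((0, 80, "camera_right"),)


def test_mirror_involution_recovers_camera_right_view():
    path = np.linspace(0, 400, 200)
    series = KeypointFrameSeries(video_id="v", keypoints=_walking_keypoints(path))
    base = center_and_scale(series)
    out_right = detect_direction_and_mirror(base.copy())
    assert np.allclose(out_right.coords, base.coords, equal_nan=True)  # no-op

    mirrored = base.copy()
    mirrored.coords[:, :, 0] *= -1
    mirrored.progression_x = -mirrored.progression_x
    for r, l in LEFT_RIGHT_PAIRS:
        mirrored.coords[:, [r, l]] = mirrored.coords[:, [l, r]]
        mirrored.missing[:, [r, l]] = mirrored.missing[:, [l, r]]
    out_mirrored = detect_direction_and_mirror(mirrored)
    assert out_mirrored.direction_segments == ((0, 200, "camera_left"),)
    assert np.allclose(out_mirrored.coords, out_right.coords, equal_nan=True)


def test_projected_angle_examples_and_atan2_oracle():
    assert projected_knee_angle((0, -1), (0, 0), (0, 1)) == pytest.approx(180.0)
    assert projected_knee_angle((0, -1), (0, 0), (1, 1)) == pytest.approx(135.0)
    assert np.isnan(projected_joint_angle((0, 0), (0, 0), (1, 1)))

    rng = np.random.default_rng(0)
    for _ in range(300):
        a, b, c = rng.normal(size=(3, 2))
        ang = projected_joint_angle(a, b, c)
        u, v = a - b, c - b
        cross = u[0] * v[1] - u[1] * v[0]
        oracle = np.degrees(abs(np.arctan2(cross, np.dot(u, v))))
        assert ang == pytest.approx(oracle, abs=1e-9)


def test_feature_series_channels_and_straight_leg():
    series = KeypointFrameSeries(video_id="v",
                                 keypoints=standing_pose_keypoints(130))
    norm = preprocess_series(series)
    feat = build_feature_series(norm, "right")
    assert feat.data.shape == (130, 12)
    assert CHANNEL_NAMES.index("knee_angle_deg") == 8
    assert np.allclose(feat.data[:, 8], 180.0, atol=1e-6)  # straight leg
    # signed ankle x-difference: ipsilateral minus contralateral
    left = build_feature_series(norm, "left")
    assert np.allclose(feat.data[:, 11], -left.data[:, 11], atol=1e-9)


def test_feature_series_errors_on_never_observed_limb():
    kp = standing_pose_keypoints(130)
    kp[:, KEYPOINT_INDEX["RAnkle"]] = 0.0
    norm = preprocess_series(KeypointFrameSeries(video_id="v", keypoints=kp))
    with pytest.raises(ValueError, match="ankle"):
        build_feature_series(norm, "right")


def test_pipeline_is_deterministic(noiseless_cohort):
    _, cohort = noiseless_cohort
    series, _ = cohort[0]
    a = preprocess_series(series)
    b = preprocess_series(series)
    assert np.array_equal(a.coords, b.coords)
    assert a.direction_segments == b.direction_segments
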