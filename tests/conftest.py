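"""Shared fixtures: hand-built keypoint series and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from videogait.io_keypoints import KEYPOINT_INDEX, KeypointFrameSeries
from videogait.synthetic_gait import SyntheticCohortConfig, simulate_cohort


def make_series(keypoints: np.ndarray, video_id: str = "v0",
                fps: float = 29.97, **kw) -> KeypointFrameSeries:
    return KeypointFrameSeries(video_id=video_id, keypoints=keypoints, fps=fps, **kw)


def standing_pose_keypoints(n_frames: int = 130) -> np.ndarray:
    """A motionless straight-legged standing subject, all keypoints detected.

    Right hip at (100, 200), right shoulder at (100, 100), so the
    normalization unit is 100 px.  Legs are vertical (straight knees).
    """
    kp = np.zeros((n_frames, 25, 3))
    pose = {
        "Nose": (105, 60), "Neck": (100, 95),
        "RShoulder": (100, 100), "LShoulder": (98, 100),
        "RElbow": (100, 140), "LElbow": (98, 140),
        "RWrist": (100, 175), "LWrist": (98, 175),
        "MidHip": (99, 200), "RHip": (100, 200), "LHip": (98, 200),
        "RKnee": (100, 250), "LKnee": (98, 250),
        "RAnkle": (100, 300), "LAnkle": (98, 300),
        "REye": (104, 55), "LEye": (103, 55), "REar": (100, 58), "LEar": (99, 58),
        "RBigToe": (112, 308), "RSmallToe": (110, 309), "RHeel": (96, 306),
        "LBigToe": (110, 308), "LSmallToe": (108, 309), "LHeel": (94, 306),
    }
    for name, (x, y) in pose.items():
        k = KEYPOINT_INDEX[name]
        kp[:, k, 0] = x
        kp[:, k, 1] = y
        kp[:, k, 2] = 0.9
    return kp


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Three healthy subjects, fixed gait parameters, no noise or dropouts."""
    cfg = SyntheticCohortConfig(
        n_patients=3, pixel_noise_sd=0.0, missing_rate=0.0,
        cadence_range=(1.0, 1.0), speed_range=(0.9, 0.9),
        severity_range=(0.0, 0.0), asymmetry_sd=0.0,
        label_noise_speed=0.0, label_noise_cadence=0.0,
        label_noise_knee=0.0, label_noise_gdi=0.0, seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort exercising every pipeline stage quickly."""
    cfg = SyntheticCohortConfig(n_patients=8, visits_per_patient=1, seed=5)
    return cfg, simulate_cohort(cfg)
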