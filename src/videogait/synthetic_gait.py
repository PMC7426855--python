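"""Synthetic sagittal-plane gait cohorts with known ground truth.

A planar linkage (pelvis, hips, knees, ankles, heels, toes, trunk,
shoulders, arms, head) is driven by periodic hip/knee/ankle angle waveforms
at a sampled cadence, with the two limbs in anti-phase.  The pelvis
translates at the sampled walking speed along a 9 m walkway and reverses
direction at the ends, so every trial exercises the mirroring logic.  A
latent severity in [0, 1] warps the knee waveform away from its nominal
shape (a crouch-like deviation), drives a GDI-like deviation score
(100 = no deviation, lower = more impaired), sets the GMFCS level by
severity quartile, and sets the SEMLS probability through a logistic link.
The world-space skeleton is projected to pixels through a panning camera
(stepped re-centering plus sinusoidal jitter), then degraded with Gaussian
pixel noise and random missing detections — emulating pose-estimator output
on a 640 × 480 video.

The waveforms are truncated-Fourier approximations of normative sagittal
joint-angle curves; the harmonic coefficients are implementation constants
below.  Realism is secondary to controllable ground truth: the GDI-like
score is a monotone proxy for gait deviation, not the clinical GDI formula
(which needs 3D kinematics and a reference population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from videogait.io_keypoints import (
    BODY_25_NAMES,
    KEYPOINT_INDEX,
    KeypointFrameSeries,
    write_labels,
    write_openpose_dir,
)

logger = logging.getLogger(__name__)

# --- skeleton geometry (meters; roughly a school-age child) ---
THIGH = 0.32
SHANK = 0.30
FOOT = 0.16
HEEL_BACK = 0.05
HIP_HEIGHT = 0.70
TORSO = 0.42          # mid-hip to neck
UPPER_ARM = 0.20
FOREARM = 0.20

# --- camera model ---
PX_PER_M = 170.0
IMAGE_CX = 320.0
GROUND_Y = 430.0      # pixel row of the ground plane (y grows downward)
PAN_HOLD_FRAMES = 30  # operator re-centers the camera every ~1 s

WALKWAY = 9.0         # meters
GDI_SLOPE = 2.7       # GDI-like points lost per degree of RMS knee deviation


@dataclass
class SyntheticCohortConfig:
    """Cohort-level generating parameters.

    Ranges are uniform sampling intervals.  ``severity_range`` draws the
    latent impairment per patient; ``asymmetry_sd`` (degrees) perturbs the
    per-limb knee offset; ``pan_amplitude`` (px) is the camera jitter.
    """

    n_patients: int = 20
    visits_per_patient: int = 1
    fps: float = 29.97
    n_frames: int = 500
    cadence_range: tuple[float, float] = (0.6, 1.3)       # strides/s
    speed_range: tuple[float, float] = (0.4, 1.4)         # m/s
    knee_flexion_offset_range: tuple[float, float] = (2.0, 25.0)  # degrees
    severity_range: tuple[float, float] = (0.0, 1.0)
    asymmetry_sd: float = 3.0
    pixel_noise_sd: float = 2.0
    missing_rate: float = 0.05
    pan_amplitude: float = 20.0
    # Clinic labels come from a separate walking session (ground truth and
    # video are not simultaneous), so the *measured* labels carry
    # trial-to-trial measurement noise on top of the video's true values.
    label_noise_speed: float = 0.06      # m/s
    label_noise_cadence: float = 0.03    # strides/s
    label_noise_knee: float = 2.5        # degrees
    label_noise_gdi: float = 3.0         # GDI-like points
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground-truth labels and noiseless waveforms of one simulated video."""

    video_id: str
    patient_id: str
    visit_id: int
    speed: float
    cadence: float
    knee_flexion_max_ext: dict[str, float]
    gdi_like: dict[str, float]
    gmfcs: str
    semls: dict[str, int]
    severity: float
    knee_offset: dict[str, float]
    #: clinic-style measured labels (video truth plus measurement noise);
    #: these are what the label table carries and what models train against
    measured: dict = field(default_factory=dict)
    waveforms: dict[str, np.ndarray] = field(default_factory=dict)
    pelvis_x_world: np.ndarray | None = None
    reversal_frames: tuple[int, ...] = ()


def _knee_nominal(phi: np.ndarray, offset: float) -> np.ndarray:
    """Nominal knee flexion (deg): swing peak near phi = 0.72, small stance
    bump, minimum (maximum extension) pinned at ``offset``."""
    b = 27.5 * (1 - np.cos(2 * np.pi * (phi - 0.72))) \
        + 6.0 * (1 - np.cos(4 * np.pi * (phi - 0.20)))
    grid = np.linspace(0, 1, 2000, endpoint=False)
    bg = 27.5 * (1 - np.cos(2 * np.pi * (grid - 0.72))) \
        + 6.0 * (1 - np.cos(4 * np.pi * (grid - 0.20)))
    return offset + (b - bg.min())


def _knee_deviation(phi: np.ndarray, severity: float) -> np.ndarray:
    """Severity-scaled crouch-like warp (deg): raised stance flexion,
    reduced dynamic range."""
    return severity * (15.0 - 10.0 * np.cos(2 * np.pi * phi))


def _ankle_wave(phi: np.ndarray) -> np.ndarray:
    """Foot pitch from horizontal (deg, toe-up positive)."""
    return 8.0 * np.sin(2 * np.pi * phi + 1.0) + 4.0 * np.sin(4 * np.pi * phi)


def gdi_like_from_severity(severity: float) -> float:
    """GDI-like score of a limb: 100 minus the RMS knee-waveform deviation
    times a fixed slope.  Strictly decreasing in severity; 100 at severity 0."""
    grid = np.linspace(0, 1, 2000, endpoint=False)
    rms = float(np.sqrt(np.mean(_knee_deviation(grid, severity) ** 2)))
    return 100.0 - GDI_SLOPE * rms


def _limb_world(phi, hip_x, hip_z, direction, knee_flex_deg, hip_flex_amp):
    """World positions of knee, ankle, toe, heel for one limb at phases phi."""
    hip_flex = np.radians(hip_flex_amp) * np.cos(2 * np.pi * phi)
    alpha = hip_flex                                  # thigh angle from vertical
    knee_x = hip_x + direction * THIGH * np.sin(alpha)
    knee_z = hip_z - THIGH * np.cos(alpha)
    beta = alpha - np.radians(knee_flex_deg)          # shank angle from vertical
    ankle_x = knee_x + direction * SHANK * np.sin(beta)
    ankle_z = knee_z - SHANK * np.cos(beta)
    gamma = np.radians(_ankle_wave(phi)) + 0.25 * beta
    toe_x = ankle_x + direction * FOOT * np.cos(gamma)
    toe_z = ankle_z - 0.05 + FOOT * np.sin(gamma)
    heel_x = ankle_x - direction * HEEL_BACK * np.cos(gamma)
    heel_z = ankle_z - 0.06
    return {
        "knee": (knee_x, knee_z), "ankle": (ankle_x, ankle_z),
        "toe": (toe_x, toe_z), "heel": (heel_x, heel_z),
    }


def _simulate_video(video_id, patient_id, visit_id, cfg: SyntheticCohortConfig,
                    rng: np.random.Generator, severity: float):
    # kinematic parameter draws; implausible stride lengths are resampled
    resamples = 0
    leg = THIGH + SHANK
    while True:
        cadence = rng.uniform(*cfg.cadence_range)
        speed = rng.uniform(*cfg.speed_range)
        stride_len = speed / cadence
        if 0.25 <= stride_len <= 2 * 0.92 * leg:
            break
        resamples += 1
        if resamples > 200:
            raise ValueError("cannot draw a kinematically plausible gait")
    if resamples:
        logger.info("%s: resampled %d implausible parameter draws", video_id, resamples)
    knee_offset_base = rng.uniform(*cfg.knee_flexion_offset_range)
    knee_offset = {
        "right": max(0.0, knee_offset_base + rng.normal(0.0, cfg.asymmetry_sd)),
        "left": max(0.0, knee_offset_base + rng.normal(0.0, cfg.asymmetry_sd)),
    }
    sev_limb = {
        "right": float(np.clip(severity * (1.0 + rng.normal(0.0, 0.08)), 0.0, 1.2)),
        "left": float(np.clip(severity * (1.0 + rng.normal(0.0, 0.08)), 0.0, 1.2)),
    }
    hip_amp = np.degrees(np.arcsin(np.clip(stride_len / (2 * leg), 0.0, 0.95)))

    T = cfg.n_frames
    t = np.arange(T) / cfg.fps
    phase0 = rng.uniform(0, 1)
    phi_r = (cadence * t + phase0) % 1.0
    phi_l = (phi_r + 0.5) % 1.0

    # pelvis progression with reversals at the walkway ends
    dt = 1.0 / cfg.fps
    x = rng.uniform(1.0, 2.0)
    direction = 1.0
    pelvis_x = np.empty(T)
    dirs = np.empty(T)
    reversals = []
    for i in range(T):
        pelvis_x[i] = x
        dirs[i] = direction
        x += direction * speed * dt
        if x >= WALKWAY - 0.5 or x <= 0.5:
            direction *= -1.0
            reversals.append(i)
    hip_z = HIP_HEIGHT + 0.015 * np.sin(4 * np.pi * phi_r)

    knee_deg = {
        s: _knee_nominal(phi, knee_offset[s]) + _knee_deviation(phi, sev_limb[s])
        for s, phi in (("right", phi_r), ("left", phi_l))
    }
    hip_x = {"right": pelvis_x + 0.01, "left": pelvis_x - 0.01}
    limbs = {
        s: _limb_world(phi, hip_x[s], hip_z, dirs, knee_deg[s], hip_amp)
        for s, phi in (("right", phi_r), ("left", phi_l))
    }

    # trunk, head, arms
    lean = np.radians(5.0 + 5.0 * severity)
    neck_x = pelvis_x + dirs * TORSO * np.sin(lean)
    neck_z = hip_z + TORSO * np.cos(lean)
    swing_r = 0.35 * np.sin(2 * np.pi * phi_l)   # arms counter the legs
    swing_l = 0.35 * np.sin(2 * np.pi * phi_r)

    world: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    world["MidHip"] = (pelvis_x, hip_z)
    world["RHip"] = (hip_x["right"], hip_z)
    world["LHip"] = (hip_x["left"], hip_z)
    for s, P in (("right", "R"), ("left", "L")):
        world[P + "Knee"] = limbs[s]["knee"]
        world[P + "Ankle"] = limbs[s]["ankle"]
        world[P + "BigToe"] = limbs[s]["toe"]
        world[P + "SmallToe"] = (limbs[s]["toe"][0] - dirs * 0.02,
                                 limbs[s]["toe"][1] + 0.005)
        world[P + "Heel"] = limbs[s]["heel"]
    world["Neck"] = (neck_x, neck_z)
    world["RShoulder"] = (neck_x + 0.02, neck_z - 0.02)
    world["LShoulder"] = (neck_x - 0.02, neck_z - 0.02)
    for P, swing in (("R", swing_r), ("L", swing_l)):
        sx, sz = world[P + "Shoulder"]
        ex = sx + dirs * UPPER_ARM * np.sin(swing)
        ez = sz - UPPER_ARM * np.cos(swing)
        world[P + "Elbow"] = (ex, ez)
        world[P + "Wrist"] = (ex + dirs * FOREARM * np.sin(swing - 0.25),
                              ez - FOREARM * np.cos(swing - 0.25))
    world["Nose"] = (neck_x + dirs * 0.09, neck_z + 0.10)
    for P in ("R", "L"):
        world[P + "Eye"] = (neck_x + dirs * 0.08, neck_z + 0.13)
        world[P + "Ear"] = (neck_x + dirs * 0.02, neck_z + 0.12)

    # camera: stepped re-centering on the pelvis plus sinusoidal jitter
    cam_x = np.empty(T)
    held = pelvis_x[0]
    for i in range(T):
        if i % PAN_HOLD_FRAMES == 0:
            held = pelvis_x[i]
        cam_x[i] = held
    jitter = cfg.pan_amplitude * np.sin(2 * np.pi * 0.07 * t + rng.uniform(0, 2 * np.pi))

    kp = np.zeros((T, 25, 3))
    for name, (wx, wz) in world.items():
        k = KEYPOINT_INDEX[name]
        kp[:, k, 0] = IMAGE_CX + PX_PER_M * (wx - cam_x) + jitter
        kp[:, k, 1] = GROUND_Y - PX_PER_M * wz
        kp[:, k, 2] = np.clip(rng.normal(0.75, 0.1, T), 0.05, 1.0)
    if cfg.pixel_noise_sd > 0:
        kp[:, :, :2] += rng.normal(0.0, cfg.pixel_noise_sd, (T, 25, 2))
    if cfg.missing_rate > 0:
        gone = rng.random((T, 25)) < cfg.missing_rate
        kp[gone] = 0.0

    series = KeypointFrameSeries(video_id=video_id, keypoints=kp, fps=cfg.fps)

    grid = np.linspace(0, 1, 2000, endpoint=False)
    knee_min = {
        s: float(np.min(_knee_nominal(grid, knee_offset[s])
                        + _knee_deviation(grid, sev_limb[s])))
        for s in ("right", "left")
    }
    gmfcs = ("I", "II", "III", "IV")[int(min(3, severity // 0.25))]
    semls = {s: int(rng.random() < 1.0 / (1.0 + np.exp(-4.0 * (sev_limb[s] - 0.5))))
             for s in ("right", "left")}
    gdi = {s: gdi_like_from_severity(sev_limb[s]) for s in ("right", "left")}
    measured = {
        "speed": speed + rng.normal(0.0, cfg.label_noise_speed),
        "cadence": cadence + rng.normal(0.0, cfg.label_noise_cadence),
        "knee_flexion_max_ext": {
            s: knee_min[s] + rng.normal(0.0, cfg.label_noise_knee)
            for s in ("right", "left")},
        "gdi_like": {s: gdi[s] + rng.normal(0.0, cfg.label_noise_gdi)
                     for s in ("right", "left")},
    }
    truth = SyntheticTruth(
        video_id=video_id, patient_id=patient_id, visit_id=visit_id,
        speed=speed, cadence=cadence,
        knee_flexion_max_ext=knee_min,
        gdi_like=gdi,
        gmfcs=gmfcs, semls=semls, severity=severity, knee_offset=knee_offset,
        measured=measured,
        waveforms={"phase": grid,
                   "knee_right": _knee_nominal(grid, knee_offset["right"])
                   + _knee_deviation(grid, sev_limb["right"]),
                   "knee_left": _knee_nominal(grid, knee_offset["left"])
                   + _knee_deviation(grid, sev_limb["left"])},
        pelvis_x_world=pelvis_x,
        reversal_frames=tuple(reversals),
    )
    return series, truth


def simulate_cohort(config: SyntheticCohortConfig
                    ) -> list[tuple[KeypointFrameSeries, SyntheticTruth]]:
    """Generate a multi-subject cohort; bit-identical for a given seed.

    Severity is drawn per patient (with a small per-visit drift), cadence
    and speed per video; stride lengths incompatible with the leg geometry
    are resampled and the count logged.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for p in range(config.n_patients):
        patient_id = f"P{p:04d}"
        severity = rng.uniform(*config.severity_range)
        for v in range(config.visits_per_patient):
            lo, hi = config.severity_range
            sev = float(np.clip(severity + rng.normal(0.0, 0.03), lo, hi))
            video_id = f"{patient_id}V{v}"
            out.append(_simulate_video(video_id, patient_id, v, config, rng, sev))
    return out


def degrade(series: KeypointFrameSeries, missing_rate: float = 0.0,
            noise_sd: float = 0.0, seed: int = 0) -> KeypointFrameSeries:
    """Add isotropic Gaussian pixel noise and random missing detections.

    Composable for robustness sweeps; rate 0 / sd 0 is the identity.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kp = series.keypoints.copy()
    present = ~series.missing_mask
    if noise_sd > 0:
        kp[:, :, :2] += np.where(present[:, :, None],
                                 rng.normal(0.0, noise_sd, kp[:, :, :2].shape), 0.0)
    if missing_rate > 0:
        gone = rng.random(present.shape) < missing_rate
        kp[gone] = 0.0
    return KeypointFrameSeries(video_id=series.video_id, keypoints=kp,
                               fps=series.fps,
                               multi_person_frames=series.multi_person_frames)


def truth_to_labels(truths: list[SyntheticTruth]) -> pd.DataFrame:
    """Assemble the cohort's label table (one row per (video, side))."""
    rows = []
    for tr in truths:
        m = tr.measured or {
            "speed": tr.speed, "cadence": tr.cadence,
            "knee_flexion_max_ext": tr.knee_flexion_max_ext,
            "gdi_like": tr.gdi_like,
        }
        rows.append({"video_id": tr.video_id, "patient_id": tr.patient_id,
                     "visit_id": tr.visit_id, "side": "none",
                     "speed": m["speed"], "cadence": m["cadence"],
                     "gmfcs": tr.gmfcs})
        for side in ("left", "right"):
            rows.append({"video_id": tr.video_id, "patient_id": tr.patient_id,
                         "visit_id": tr.visit_id, "side": side,
                         "knee_flexion_max_ext": m["knee_flexion_max_ext"][side],
                         "gdi": m["gdi_like"][side], "semls": tr.semls[side]})
    return pd.DataFrame(rows)


def write_cohort(cohort: list[tuple[KeypointFrameSeries, SyntheticTruth]],
                 path: str | Path) -> None:
    """Write a cohort as OpenPose-format JSON directories plus labels.csv,
    so synthetic data flows through the same ingestion path as real data."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for series, _ in cohort:
        write_openpose_dir(series, path / series.video_id)
    write_labels(truth_to_labels([t for _, t in cohort]), path / "labels.csv")
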