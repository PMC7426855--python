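"""Normalization of raw keypoint trajectories into model-ready feature series.

The chain converts pixel-space BODY_25 trajectories into a 12-channel
multivariate time series per limb:

1. :func:`center_and_scale` — per frame, subtract the right-hip position and
   divide by the right-hip→right-shoulder Euclidean distance, removing camera
   translation and projection scale.
2. :func:`detect_direction_and_mirror` — segment the trial into
   constant-walking-direction runs and mirror camera-left runs (negate x,
   swap anatomical left/right labels) so every frame presents a right-side
   view or a mirrored left-side view.
3. :func:`smooth_gaussian` — missing-aware Gaussian smoothing along time
   (default sigma = 1 frame), applied after mirroring so x-channels are
   continuous across reversal boundaries.
4. :func:`impute_linear` — linear interpolation of interior gaps, edge-hold
   at the boundaries; the pre-imputation mask is retained for the windowing
   stage's missing-fraction rule.

Coordinates use the pixel convention (x rightward, y downward), so on a
right-side view the subject walks toward +x and "up" is -y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from videogait.io_keypoints import (
    KEYPOINT_INDEX,
    LEFT_RIGHT_PAIRS,
    KeypointFrameSeries,
)

CAMERA_RIGHT = "camera_right"
CAMERA_LEFT = "camera_left"

#: Fixed order and names of the 12 model input channels (per limb).
CHANNEL_NAMES: tuple[str, ...] = (
    "ankle_x", "ankle_y", "knee_x", "knee_y", "hip_x", "hip_y",
    "bigtoe_x", "bigtoe_y", "knee_angle_deg", "ankle_angle_deg",
    "toe_ankle_dist", "ankle_x_diff",
)


@dataclass
class NormalizedSeries:
    """Dimensionless, hip-centered keypoint trajectories of one trial.

    ``coords`` is (T, 25, 2) with NaN at missing samples; the unit of length
    is the per-frame right-hip→right-shoulder distance.  ``progression_x``
    keeps the raw mid-hip pixel x-coordinate for walking-direction detection
    (centering erases progression).  ``direction_segments`` is a tuple of
    ``(start, end, direction)`` half-open runs, where ``direction`` records
    the walking direction *observed in the input* before any mirroring.
    """

    video_id: str
    coords: np.ndarray
    missing: np.ndarray
    progression_x: np.ndarray
    fps: float = 29.97
    direction_segments: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)
    pre_imputation_missing: np.ndarray | None = None
    direction_warning: bool = False

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "NormalizedSeries":
        return replace(
            self,
            coords=self.coords.copy(),
            missing=self.missing.copy(),
            progression_x=self.progression_x.copy(),
            pre_imputation_missing=None if self.pre_imputation_missing is None
            else self.pre_imputation_missing.copy(),
        )


@dataclass
class FeatureSeries:
    """The 12-channel normalized time series fed to models, for one limb.

    Channels, in fixed order: ipsilateral ankle (x, y), knee (x, y),
    hip (x, y), big toe (x, y); projected knee flexion angle and projected
    ankle angle in degrees; big-toe–ankle Euclidean distance; and the signed
    ipsilateral-minus-contralateral ankle x-difference.  After imputation no
    missing values remain in ``data``; ``channel_missing`` carries the
    pre-imputation missingness of each channel's underlying keypoints.
    """

    video_id: str
    side: str
    data: np.ndarray
    channel_missing: np.ndarray
    fps: float = 29.97

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.data, columns=list(CHANNEL_NAMES))


_R_HIP = KEYPOINT_INDEX["RHip"]
_R_SHOULDER = KEYPOINT_INDEX["RShoulder"]
_MID_HIP = KEYPOINT_INDEX["MidHip"]


def center_and_scale(series: KeypointFrameSeries) -> NormalizedSeries:
    """Center on the right hip and scale by the hip–shoulder distance, per frame.

    Frames where the right hip or right shoulder is missing — or where the
    two coincide (degenerate pose, zero scale) — yield missing normalized
    coordinates for the whole frame; they are filled later by imputation.
    """
    kp = series.keypoints
    raw_missing = series.missing_mask
    hip = kp[:, _R_HIP, :2]
    shoulder = kp[:, _R_SHOULDER, :2]
    scale = np.linalg.norm(hip - shoulder, axis=1)
    frame_bad = raw_missing[:, _R_HIP] | raw_missing[:, _R_SHOULDER] | (scale <= 1e-9)
    if frame_bad.all():
        raise ValueError(
            f"{series.video_id}: right hip and shoulder never jointly detected"
        )
    safe_scale = np.where(frame_bad, 1.0, scale)
    coords = (kp[:, :, :2] - hip[:, None, :]) / safe_scale[:, None, None]
    missing = raw_missing | frame_bad[:, None]
    coords = np.where(missing[:, :, None], np.nan, coords)
    progression = np.where(raw_missing[:, _MID_HIP], np.nan, kp[:, _MID_HIP, 0])
    return NormalizedSeries(
        video_id=series.video_id,
        coords=coords,
        missing=missing,
        progression_x=progression,
        fps=series.fps,
    )


def _interp_nan(values: np.ndarray) -> np.ndarray:
    """1-D linear interpolation over NaN with edge-hold; all-NaN stays NaN."""
    out = values.astype(float).copy()
    obs = np.flatnonzero(~np.isnan(out))
    if obs.size == 0:
        return out
    t = np.arange(out.size)
    out = np.interp(t, obs, out[obs])
    return out


def smooth_gaussian(series: NormalizedSeries, sigma: float = 1.0,
                    truncate: float = 4.0) -> NormalizedSeries:
    """Missing-aware Gaussian smoothing along time of every coordinate channel.

    Missing samples are excluded from the convolution: each output value is
    the Gaussian-weighted average of the *available* neighbors (weights
    renormalized by their sum).  Missing positions remain missing.
    """
    if sigma <= 0:
        return series.copy()
    out = series.copy()
    w = (~series.missing).astype(float)  # (T, 25)
    vals = np.nan_to_num(series.coords, nan=0.0) * w[:, :, None]
    num = ndimage.gaussian_filter1d(vals, sigma=sigma, axis=0, mode="nearest",
                                    truncate=truncate)
    den = ndimage.gaussian_filter1d(w, sigma=sigma, axis=0, mode="nearest",
                                    truncate=truncate)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den[:, :, None]
    out.coords = np.where(series.missing[:, :, None], np.nan, smoothed)
    return out


def impute_linear(series: NormalizedSeries) -> NormalizedSeries:
    """Fill missing samples by linear interpolation (edge-hold at boundaries).

    Keypoints never observed at all remain missing and are reported by the
    feature builder.  The pre-imputation mask is preserved on the result for
    the windowing stage's missing-fraction rule.
    """
    out = series.copy()
    if out.pre_imputation_missing is None:
        out.pre_imputation_missing = series.missing.copy()
    coords = out.coords
    for k in range(coords.shape[1]):
        for d in range(2):
            coords[:, k, d] = _interp_nan(coords[:, k, d])
    out.missing = np.isnan(coords).any(axis=2)
    return out


def _mirror_inplace(series: NormalizedSeries, start: int, end: int) -> None:
    series.coords[start:end, :, 0] *= -1.0
    for r, l in LEFT_RIGHT_PAIRS:
        for arr in (series.coords, series.missing, series.pre_imputation_missing):
            if arr is None:
                continue
            tmp = arr[start:end, r].copy()
            arr[start:end, r] = arr[start:end, l]
            arr[start:end, l] = tmp


def detect_direction_and_mirror(
    series: NormalizedSeries,
    velocity_window: int = 15,
    min_run: int = 30,
) -> NormalizedSeries:
    """Segment the trial by walking direction and mirror camera-left runs.

    The walking direction is the sign of the mid-hip pixel x-velocity,
    median-filtered over a sliding ``velocity_window``-frame window (the
    median is robust to the velocity spikes a panning camera introduces);
    runs shorter than ``min_run`` frames are merged into their neighbors.
    Runs walking toward camera-left have x negated and anatomical left/right
    keypoint labels swapped, so the output always presents a right-side (or
    mirrored-left) view.  If the direction cannot be determined (subject
    stationary), the series is returned unmirrored as a single run with
    ``direction_warning`` set.
    """
    out = series.copy()
    T = out.n_frames
    px = _interp_nan(out.progression_x)
    if np.isnan(px).any() or T < 2:
        out.direction_segments = ((0, T, CAMERA_RIGHT),)
        out.direction_warning = True
        return out
    vel = np.gradient(px)
    vel = ndimage.median_filter(vel, size=min(velocity_window, T), mode="nearest")
    sign = np.sign(vel)
    # zero-velocity samples inherit the nearest preceding (then following) sign
    nz = np.flatnonzero(sign != 0)
    if nz.size == 0:
        out.direction_segments = ((0, T, CAMERA_RIGHT),)
        out.direction_warning = True
        return out
    idx = np.arange(T)
    prev = np.maximum.accumulate(np.where(sign != 0, idx, -1))
    filled = np.where(prev >= 0, sign[np.maximum(prev, 0)], sign[nz[0]])
    # runs of constant sign
    bounds = np.flatnonzero(np.diff(filled) != 0) + 1
    runs = [[s, e, filled[s]] for s, e in
            zip(np.r_[0, bounds], np.r_[bounds, T])]
    # merge short runs into the longer adjacent neighbor
    while len(runs) > 1:
        lengths = [e - s for s, e, _ in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_run:
            break
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if (runs[i - 1][1] - runs[i - 1][0]) >= (runs[i + 1][1] - runs[i + 1][0]) else i + 1
        lo, hi = min(i, j), max(i, j)
        runs[lo:hi + 1] = [[runs[lo][0], runs[hi][1], runs[j][2]]]
    # coalesce equal-sign neighbors
    merged: list[list] = []
    for run in runs:
        if merged and merged[-1][2] == run[2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments = []
    for s, e, sgn in merged:
        direction = CAMERA_RIGHT if sgn > 0 else CAMERA_LEFT
        if direction == CAMERA_LEFT:
            _mirror_inplace(out, s, e)
        segments.append((int(s), int(e), direction))
    out.direction_segments = tuple(segments)
    return out


def projected_joint_angle(a: np.ndarray, vertex: np.ndarray,
                          c: np.ndarray) -> np.ndarray:
    """Unsigned image-plane angle at ``vertex`` between rays to ``a`` and ``c``.

    Returns degrees in [0, 180].  Coincident points make the angle undefined
    and yield NaN.  Inputs may be single points or (T, 2) stacks.
    """
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - vertex
    v = c - vertex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where((nu <= 1e-12) | (nv <= 1e-12), np.nan, ang)


def projected_knee_angle(hip, knee, ankle) -> np.ndarray:
    """Projected knee angle: angle between knee→hip and knee→ankle vectors.

    180 degrees is a straight leg; knee *flexion* is 180 minus this value.
    """
    return projected_joint_angle(hip, knee, ankle)


_SIDE_PREFIX = {"left": "L", "right": "R"}


def build_feature_series(series: NormalizedSeries, side: str) -> FeatureSeries:
    """Assemble the 12-channel input series for one limb.

    Requires a centered, direction-aligned, imputed series.  The ankle
    x-difference channel is signed, ipsilateral minus contralateral.  Angle
    and distance channels are computed from the imputed coordinates; a
    channel whose underlying keypoint was never observed raises.
    """
    if side not in _SIDE_PREFIX:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    p = _SIDE_PREFIX[side]
    q = _SIDE_PREFIX["left" if side == "right" else "right"]
    idx = {
        "ankle": KEYPOINT_INDEX[p + "Ankle"],
        "knee": KEYPOINT_INDEX[p + "Knee"],
        "hip": KEYPOINT_INDEX[p + "Hip"],
        "bigtoe": KEYPOINT_INDEX[p + "BigToe"],
        "contra_ankle": KEYPOINT_INDEX[q + "Ankle"],
    }
    pre = (series.pre_imputation_missing
           if series.pre_imputation_missing is not None else series.missing)
    for name, k in idx.items():
        if np.isnan(series.coords[:, k]).all():
            raise ValueError(
                f"{series.video_id}/{side}: keypoint for channel {name!r} never observed"
            )
    coords = series.coords
    ankle = coords[:, idx["ankle"]]
    knee = coords[:, idx["knee"]]
    hip = coords[:, idx["hip"]]
    toe = coords[:, idx["bigtoe"]]
    contra = coords[:, idx["contra_ankle"]]
    T = series.n_frames
    data = np.empty((T, 12))
    data[:, 0:2] = ankle
    data[:, 2:4] = knee
    data[:, 4:6] = hip
    data[:, 6:8] = toe
    data[:, 8] = projected_joint_angle(hip, knee, ankle)
    data[:, 9] = projected_joint_angle(knee, ankle, toe)
    data[:, 10] = np.linalg.norm(toe - ankle, axis=1)
    data[:, 11] = ankle[:, 0] - contra[:, 0]
    miss = np.empty((T, 12), dtype=bool)
    miss[:, 0:2] = pre[:, [idx["ankle"]]]
    miss[:, 2:4] = pre[:, [idx["knee"]]]
    miss[:, 4:6] = pre[:, [idx["hip"]]]
    miss[:, 6:8] = pre[:, [idx["bigtoe"]]]
    miss[:, 8] = pre[:, idx["hip"]] | pre[:, idx["knee"]] | pre[:, idx["ankle"]]
    miss[:, 9] = pre[:, idx["knee"]] | pre[:, idx["ankle"]] | pre[:, idx["bigtoe"]]
    miss[:, 10] = pre[:, idx["bigtoe"]] | pre[:, idx["ankle"]]
    miss[:, 11] = pre[:, idx["ankle"]] | pre[:, idx["contra_ankle"]]
    return FeatureSeries(video_id=series.video_id, side=side, data=data,
                         channel_missing=miss, fps=series.fps)


def preprocess_series(series: KeypointFrameSeries,
                      sigma: float = 1.0) -> NormalizedSeries:
    """Full normalization chain: center/scale → mirror → smooth → impute."""
    norm = center_and_scale(series)
    norm = detect_direction_and_mirror(norm)
    norm = smooth_gaussian(norm, sigma=sigma)
    return impute_linear(norm)
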