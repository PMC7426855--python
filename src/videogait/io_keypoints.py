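"""Reading and writing pose-keypoint data and clinical label tables.

Raw input is the OpenPose BODY_25 convention: one JSON file per video frame,
each holding, per detected person, a flat ``pose_keypoints_2d`` list of
25 × (x, y, confidence) triplets in image-plane pixels.  Image coordinates
follow the pixel convention everywhere in this package: x grows rightward,
y grows *downward*, origin at the top-left of the frame.

A detection is *missing* when its confidence is 0 or its coordinates are
exactly (0, 0) — OpenPose emits (0, 0, 0) for undetected keypoints, and both
encodings occur in practice.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 25 BODY_25 landmark names in OpenPose output order.
BODY_25_NAMES: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(BODY_25_NAMES)}

#: Anatomical left/right partner indices, used when mirroring a series.
LEFT_RIGHT_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (KEYPOINT_INDEX["R" + stem], KEYPOINT_INDEX["L" + stem])
    for stem in ("Shoulder", "Elbow", "Wrist", "Hip", "Knee", "Ankle",
                 "Eye", "Ear", "BigToe", "SmallToe", "Heel")
)

GMFCS_LEVELS: tuple[str, ...] = ("I", "II", "III", "IV")

SIDES: tuple[str, ...] = ("left", "right", "none")

#: Label-table fields that are defined per limb vs per video.
LIMB_FIELDS = ("knee_flexion_max_ext", "gdi", "semls")
VIDEO_FIELDS = ("speed", "cadence", "gmfcs")


class FormatError(ValueError):
    """A file failed to parse as the expected on-disk format."""


@dataclass
class KeypointFrameSeries:
    """Raw per-frame 25-keypoint pixel trajectories of one video trial.

    ``keypoints`` has shape (n_frames, 25, 3) with columns (x px, y px,
    confidence in [0, 1]).  ``multi_person_frames`` lists frame indices where
    OpenPose detected more than one person; such videos are excluded from
    analysis at the video level (see :func:`filter_analyzable`).
    """

    video_id: str
    keypoints: np.ndarray
    fps: float = 29.97
    multi_person_frames: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (25, 3):
            raise ValueError(
                f"keypoints must have shape (T, 25, 3); got {self.keypoints.shape}"
            )
        if self.keypoints.shape[0] < 1:
            raise ValueError("a series needs at least one frame")
        conf = self.keypoints[:, :, 2]
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """(T, 25) boolean mask; True where the detection carries no information."""
        xy_zero = (self.keypoints[:, :, 0] == 0.0) & (self.keypoints[:, :, 1] == 0.0)
        return (self.keypoints[:, :, 2] == 0.0) | xy_zero


_FRAME_INDEX_RE = re.compile(r"(\d+)_keypoints\.json$|(\d+)\.json$")


def _frame_index(path: Path) -> int:
    m = _FRAME_INDEX_RE.search(path.name)
    if m is None:
        raise FormatError(f"cannot extract a frame index from file name {path.name!r}")
    return int(m.group(1) or m.group(2))


def read_openpose_dir(path: str | Path, fps: float = 29.97,
                      video_id: str | None = None) -> KeypointFrameSeries:
    """Read a directory of per-frame OpenPose BODY_25 JSON files.

    Frames are ordered by the frame index embedded in the file name,
    regardless of filesystem listing order.  A frame with no detected people
    has all 25 keypoints marked missing.  When more than one person is
    detected in a frame, the person with the highest total confidence is
    retained and the frame is recorded in ``multi_person_frames`` so the
    video-level filter can exclude the trial.
    """
    path = Path(path)
    files = sorted(path.glob("*.json"), key=_frame_index)
    if not files:
        raise FileNotFoundError(f"no per-frame JSON files in {path}")
    frames = []
    multi = []
    for i, f in enumerate(files):
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"unparseable OpenPose JSON: {f}") from exc
        people = doc.get("people", [])
        if not people:
            frames.append(np.zeros((25, 3)))
            continue
        if len(people) > 1:
            multi.append(i)
        best = max(
            people,
            key=lambda p: float(np.sum(np.asarray(p["pose_keypoints_2d"])[2::3])),
        )
        arr = np.asarray(best["pose_keypoints_2d"], dtype=float)
        if arr.size != 75:
            raise FormatError(
                f"{f}: expected 75 values in pose_keypoints_2d, got {arr.size}"
            )
        frames.append(arr.reshape(25, 3))
    return KeypointFrameSeries(
        video_id=video_id if video_id is not None else path.name,
        keypoints=np.stack(frames),
        fps=fps,
        multi_person_frames=tuple(multi),
    )


def write_openpose_dir(series: KeypointFrameSeries, path: str | Path) -> None:
    """Write a series as a directory of per-frame OpenPose-format JSON files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    missing = series.missing_mask
    for t in range(series.n_frames):
        if missing[t].all():
            people = []
        else:
            people = [{"person_id": [-1],
                       "pose_keypoints_2d": series.keypoints[t].ravel().tolist()}]
        doc = {"version": 1.3, "people": people}
        (path / f"{series.video_id}_{t:012d}_keypoints.json").write_text(json.dumps(doc))


def filter_analyzable(series: KeypointFrameSeries) -> bool:
    """Whether a video can enter the analysis.

    Videos where more than one person was ever visible, or where the subject
    was never detected at all, are excluded (matching the study's video-level
    exclusion rule).
    """
    if series.multi_person_frames:
        return False
    if series.missing_mask.all():
        return False
    return True


def _validate_labels(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("video_id", "side"):
        if col not in df.columns:
            raise FormatError(f"labels table is missing required column {col!r}")
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        raise FormatError(f"invalid side values: {sorted(df.loc[bad_side, 'side'].unique())}")
    if "gmfcs" in df.columns:
        vals = df["gmfcs"].dropna()
        bad = ~vals.astype(str).isin(GMFCS_LEVELS)
        if bad.any():
            raise FormatError(
                f"gmfcs outside I-IV: {sorted(vals[bad].astype(str).unique())}"
            )
    for fld in VIDEO_FIELDS:
        if fld in df.columns:
            misplaced = df[fld].notna() & (df["side"] != "none")
            if misplaced.any():
                raise FormatError(f"side-independent field {fld!r} on a limb row")
    for fld in LIMB_FIELDS:
        if fld in df.columns:
            misplaced = df[fld].notna() & (df["side"] == "none")
            if misplaced.any():
                raise FormatError(f"limb-specific field {fld!r} on a side='none' row")
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a clinical label table (CSV, one row per (video, side)).

    Columns: ``video_id, side`` (required), optional ``patient_id, visit_id``
    and any of ``speed`` (m/s), ``cadence`` (strides/s),
    ``knee_flexion_max_ext`` (degrees), ``gdi``, ``gmfcs`` (I-IV),
    ``semls`` (0/1).  Unknown columns are preserved.
    """
    df = pd.read_csv(path, dtype={"video_id": str, "side": str, "gmfcs": str})
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].astype(str)
    return _validate_labels(df)


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    """Write a label table as UTF-8 comma-separated CSV ('.' decimal)."""
    _validate_labels(df)
    df.to_csv(path, index=False)


def gmfcs_to_int(level: str) -> int:
    """Map an ordinal GMFCS level 'I'..'IV' to 1..4."""
    try:
        return GMFCS_LEVELS.index(str(level)) + 1
    except ValueError:
        raise ValueError(f"GMFCS level must be one of {GMFCS_LEVELS}, got {level!r}")
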