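"""Window-slicing augmentation: fixed-length training segments from full trials.

A trial's 12-channel feature series is cut into overlapping 124-frame windows
separated by a 31-frame stride; each window inherits the trial's label.
Windows with more than 25% of their pre-imputation cells missing are dropped.
The per-video retained-segment count c(i) is kept for loss weighting (each
video's total loss contribution is divided by c(i)) and for averaging segment
predictions back to a per-video value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from videogait.preprocess import FeatureSeries

WINDOW = 124
STRIDE = 31
MAX_MISSING = 0.25


@dataclass
class Segment:
    """One fixed-length training window of a video's feature series."""

    video_id: str
    side: str
    start_frame: int
    data: np.ndarray
    missing_fraction: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")


@dataclass
class SegmentSet:
    """A collection of segments with per-video bookkeeping.

    ``c`` maps video_id to the number of retained segments of that video and
    ``labels`` maps video_id to its target value; both limbs of a
    side-independent target share one video_id, one c(i) and one label.
    """

    segments: list[Segment] = field(default_factory=list)
    c: dict[str, int] = field(default_factory=dict)
    labels: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def weights(self) -> np.ndarray:
        """Per-segment loss weights 1/c(i), aligned with ``segments``."""
        return np.array([1.0 / self.c[s.video_id] for s in self.segments])

    def y(self) -> np.ndarray:
        return np.array([self.labels[s.video_id] for s in self.segments])


def slice_windows(feature: FeatureSeries, window: int = WINDOW,
                  stride: int = STRIDE) -> list[Segment]:
    """Cut a feature series into overlapping fixed-length windows.

    Starts are 0, stride, 2·stride, … while start + window <= T, so a clean
    500-frame trial yields 13 windows starting at {0, 31, …, 372}.  Each
    window carries the fraction of its pre-imputation cells that were
    missing.  A series shorter than one window yields an empty list.
    """
    T = feature.n_frames
    if T < window:
        warnings.warn(
            f"{feature.video_id}/{feature.side}: {T} frames < window {window}; no segments"
        )
        return []
    segments = []
    for start in range(0, T - window + 1, stride):
        block = feature.data[start:start + window]
        miss = feature.channel_missing[start:start + window]
        segments.append(Segment(
            video_id=feature.video_id,
            side=feature.side,
            start_frame=start,
            data=block.copy(),
            missing_fraction=float(np.mean(miss)),
        ))
    return segments


def filter_missing(segments: list[Segment],
                   max_missing: float = MAX_MISSING) -> list[Segment]:
    """Drop segments with *more than* ``max_missing`` of their data missing.

    The inequality is strict: a segment at exactly 25.0% missing is retained.
    """
    return [s for s in segments if s.missing_fraction <= max_missing]


def build_segment_set(videos: list[tuple[FeatureSeries, float]],
                      window: int = WINDOW, stride: int = STRIDE,
                      max_missing: float = MAX_MISSING) -> SegmentSet:
    """Slice, filter and label a list of (feature series, target) pairs.

    Multiple feature series may share a video_id (both limbs of a
    side-independent target); their segments pool under one c(i).  A video
    whose every window exceeds the missing threshold is excluded and listed
    in ``excluded``.
    """
    out = SegmentSet()
    pending: dict[str, list[Segment]] = {}
    label_of: dict[str, float] = {}
    for feature, y in videos:
        kept = filter_missing(slice_windows(feature, window, stride), max_missing)
        pending.setdefault(feature.video_id, []).extend(kept)
        if feature.video_id in label_of and label_of[feature.video_id] != y:
            raise ValueError(f"conflicting labels for video {feature.video_id!r}")
        label_of[feature.video_id] = y
    for vid, segs in pending.items():
        if not segs:
            out.excluded.append(vid)
            continue
        out.segments.extend(segs)
        out.c[vid] = len(segs)
        out.labels[vid] = label_of[vid]
    return out
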