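"""Motion-quantity time series from consecutive 2D poses.

For a video sampled as poses ``P_1, ..., P_F`` (each 17 keypoints), the
motion quantity between consecutive poses is the sum of per-keypoint
Euclidean displacements::

    S_i = sum_{k=1..17} || P_{i+1,k} - P_{i,k} ||_2        (pixels)

so a series of ``F`` pose frames yields ``F - 1`` motion values, the value at
index ``i`` being attached to the leading frame's timestamp. Units are raw
pixels: no normalisation by image size or infant scale is applied.

Low-confidence keypoints can optionally be excluded via a
:class:`ConfidencePolicy`; the default policy includes every keypoint, which
reproduces the plain displacement sum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParseError, SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .pose_io import PoseFrame, PoseSeries

ConfidenceMode = Literal["include_all", "drop_keypoint", "normalize"]

_MOTION_CSV_COLUMNS = ["video_id", "time_s", "motion_quantity"]


@dataclass(frozen=True)
class ConfidencePolicy:
    """How low-confidence keypoints enter the displacement sum.

    * ``include_all`` — every keypoint contributes (the literal formula).
    * ``drop_keypoint`` — only keypoints with confidence >= ``threshold``
      in *both* frames of a pair contribute.
    * ``normalize`` — as ``drop_keypoint``, with the sum rescaled by
      ``17 / n_retained`` so values remain comparable across frames; a pair
      retaining no keypoint scores 0 by convention.
    """

    threshold: float = 0.0
    mode: ConfidenceMode = "include_all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.mode not in ("include_all", "drop_keypoint", "normalize"):
            raise ValueError(f"unknown confidence mode {self.mode!r}")


DEFAULT_POLICY = ConfidencePolicy()


@dataclass(eq=False)
class MotionSeries:
    """Scalar motion quantity per consecutive-frame pair, in pixels."""

    video_id: str
    values: np.ndarray
    sample_rate_hz: float
    t0_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SchemaError("motion values must be a 1-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise SchemaError("motion values must be finite and >= 0")
        if self.sample_rate_hz <= 0:
            raise SchemaError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Timestamp of each value's leading frame, in seconds."""
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz


def _pair_displacements(
    coords: np.ndarray, confidence: np.ndarray, policy: ConfidencePolicy
) -> np.ndarray:
    """Vectorised per-pair displacement sums for ``(n, 17, 2)`` coords."""
    dist = np.linalg.norm(coords[1:] - coords[:-1], axis=2)  # (n-1, 17)
    if policy.mode == "include_all":
        return dist.sum(axis=1)
    keep = (confidence[:-1] >= policy.threshold) & (confidence[1:] >= policy.threshold)
    total = (dist * keep).sum(axis=1)
    if policy.mode == "drop_keypoint":
        return total
    retained = keep.sum(axis=1)
    n_kp = coords.shape[1]
    return np.where(retained > 0, total * n_kp / np.maximum(retained, 1), 0.0)


def frame_displacement(
    a: "PoseFrame", b: "PoseFrame", policy: ConfidencePolicy = DEFAULT_POLICY
) -> float:
    """Summed Euclidean keypoint displacement between two poses, in pixels."""
    coords = np.stack([a.xy, b.xy])
    conf = np.stack([a.confidences, b.confidences])
    return float(_pair_displacements(coords, conf, policy)[0])


def motion_series(
    series: "PoseSeries", policy: ConfidencePolicy = DEFAULT_POLICY
) -> MotionSeries:
    """Compute the motion-quantity series of a pose series.

    ``values[i]`` is the displacement between frames ``i`` and ``i + 1``;
    the sampling rate is inherited from the pose series.
    """
    if series.n_frames < 2:
        raise InsufficientDataError(
            "motion computation requires at least 2 pose frames"
        )
    values = _pair_displacements(series.coords, series.confidence, policy)
    return MotionSeries(
        video_id=series.video_id,
        values=values,
        sample_rate_hz=series.sample_rate_hz,
        t0_s=float(series.times[0]),
    )


def write_motion_csv(motion: MotionSeries, path: str | Path) -> None:
    """Export with header ``video_id,time_s,motion_quantity``.

    Values are written with shortest round-trip float formatting so the file
    is bit-faithful to the in-memory series.
    """
    pd.DataFrame(
        {
            "video_id": motion.video_id,
            "time_s": [repr(float(t)) for t in motion.times],
            "motion_quantity": [repr(float(v)) for v in motion.values],
        }
    ).to_csv(path, index=False)


def read_motion_csv(path: str | Path) -> MotionSeries:
    """Read a motion CSV written by :func:`write_motion_csv`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MOTION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: motion series contains no values")
    video_ids = df["video_id"].unique()
    if len(video_ids) != 1:
        raise SchemaError(f"{path}: expected a single video_id")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) == 1:
        rate = 1.0
    else:
        gaps = np.diff(times)
        if np.any(gaps <= 0):
            raise ParseError(f"{path}: rows out of time order")
        rate = 1.0 / float(np.median(gaps))
    return MotionSeries(
        video_id=str(video_ids[0]),
        values=df["motion_quantity"].to_numpy(dtype=float),
        sample_rate_hz=rate,
        t0_s=float(times[0]),
    )
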