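"""Reading and writing keypoint time series and expert annotations.

The toolkit exchanges two tabular formats with upstream pose estimators and
human raters:

* **Keypoint CSV** — header ``video_id,time_s,kp_index,kp_name,x,y,confidence``,
  one row per keypoint per frame, ``kp_index`` 0–16 in COCO-17 order.
* **COCO-style keypoint JSON** — a list of per-frame objects, each carrying
  ``video_id``, ``time_s`` and a flat 51-value ``keypoints`` array ordered
  ``(x, y, confidence) × 17``.
* **Annotation CSV** — header ``rater_id,video_id,start_s,end_s`` with
  half-open interval semantics.

Coordinates are pixels in the image frame; a missing detection is encoded by
``confidence = 0`` (with repeated or ``(0, 0)`` coordinates), never by
non-finite values. Timestamps are stored as seconds; frame indices are always
derived, never stored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    ParseError,
    ResamplingError,
    SamplingError,
    SchemaError,
)
from .intervals import TimeInterval

#: COCO-17 keypoint names, the fixed anatomical order used throughout.
COCO17_KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_KEYPOINTS = 17

#: Tolerance on inter-frame time gaps (seconds) for uniform-sampling checks.
TIME_TOLERANCE_S = 1e-6

PoseFormat = Literal["csv", "coco_json"]

_POSE_CSV_COLUMNS = ["video_id", "time_s", "kp_index", "kp_name", "x", "y", "confidence"]
_ANNOTATION_COLUMNS = ["rater_id", "video_id", "start_s", "end_s"]


@dataclass(frozen=True)
class Keypoint:
    """A single 2D body landmark with detector confidence."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("keypoint coordinates must be finite")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PoseFrame:
    """One sampled pose: a timestamp plus exactly 17 ordered keypoints."""

    time_s: float
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("frame time must be >= 0")
        if len(self.keypoints) != N_KEYPOINTS:
            raise ValueError(
                f"a pose frame requires exactly {N_KEYPOINTS} keypoints, "
                f"got {len(self.keypoints)}"
            )

    @property
    def xy(self) -> np.ndarray:
        """Coordinates as a ``(17, 2)`` float array."""
        return np.array([[kp.x, kp.y] for kp in self.keypoints], dtype=float)

    @property
    def confidences(self) -> np.ndarray:
        """Confidences as a ``(17,)`` float array."""
        return np.array([kp.confidence for kp in self.keypoints], dtype=float)


@dataclass(eq=False)
class PoseSeries:
    """A uniformly sampled sequence of 17-keypoint 2D poses.

    Internally array-backed: ``times`` is ``(n,)``, ``coords`` is
    ``(n, 17, 2)`` (pixels) and ``confidence`` is ``(n, 17)``. Frames are
    strictly increasing in time with gaps equal to ``1/sample_rate_hz``
    within :data:`TIME_TOLERANCE_S`.
    """

    video_id: str
    times: np.ndarray
    coords: np.ndarray
    confidence: np.ndarray
    sample_rate_hz: float
    frame_width_px: int | None = None
    frame_height_px: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = self.times.shape[0]
        if n < 2:
            raise SchemaError("a pose series requires at least 2 frames")
        if self.coords.shape != (n, N_KEYPOINTS, 2):
            raise SchemaError(
                f"coords must have shape ({n}, {N_KEYPOINTS}, 2), got {self.coords.shape}"
            )
        if self.confidence.shape != (n, N_KEYPOINTS):
            raise SchemaError(
                f"confidence must have shape ({n}, {N_KEYPOINTS}), "
                f"got {self.confidence.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError("keypoint coordinates must be finite")
        if not np.all(np.isfinite(self.times)) or self.times[0] < 0:
            raise SchemaError("frame times must be finite and >= 0")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise SchemaError("confidences must lie in [0, 1]")
        if self.sample_rate_hz <= 0:
            raise SchemaError("sample_rate_hz must be positive")
        gaps = np.diff(self.times)
        if np.any(gaps <= 0):
            raise SamplingError("frame times must be strictly increasing")
        expected = 1.0 / self.sample_rate_hz
        if np.any(np.abs(gaps - expected) > TIME_TOLERANCE_S):
            raise SamplingError(
                f"frame gaps deviate from 1/sample_rate_hz = {expected:.6g} s "
                f"by more than {TIME_TOLERANCE_S} s"
            )
        for dim, name in ((self.frame_width_px, "frame_width_px"),
                          (self.frame_height_px, "frame_height_px")):
            if dim is not None and dim <= 0:
                raise SchemaError(f"{name} must be positive when given")

    # -- frame views --------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> PoseFrame:
        kps = tuple(
            Keypoint(float(x), float(y), float(c))
            for (x, y), c in zip(self.coords[i], self.confidence[i])
        )
        return PoseFrame(time_s=float(self.times[i]), keypoints=kps)

    def frames(self) -> Iterator[PoseFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    @classmethod
    def from_frames(
        cls,
        video_id: str,
        frames: Sequence[PoseFrame],
        frame_width_px: int | None = None,
        frame_height_px: int | None = None,
    ) -> "PoseSeries":
        """Build a series from frame objects, inferring the sample rate."""
        if len(frames) < 2:
            raise SchemaError("a pose series requires at least 2 frames")
        times = np.array([f.time_s for f in frames], dtype=float)
        rate = _infer_rate(times)
        coords = np.stack([f.xy for f in frames])
        conf = np.stack([f.confidences for f in frames])
        return cls(
            video_id=video_id,
            times=times,
            coords=coords,
            confidence=conf,
            sample_rate_hz=rate,
            frame_width_px=frame_width_px,
            frame_height_px=frame_height_px,
        )

    def equals(self, other: "PoseSeries", atol: float = 1e-6) -> bool:
        """Element-wise equality within ``atol`` on coordinates, confidences
        and times (the round-trip contract at 6-decimal file precision)."""
        return (
            self.video_id == other.video_id
            and self.n_frames == other.n_frames
            and np.allclose(self.times, other.times, atol=atol, rtol=0)
            and np.allclose(self.coords, other.coords, atol=atol, rtol=0)
            and np.allclose(self.confidence, other.confidence, atol=atol, rtol=0)
            and math.isclose(
                1.0 / self.sample_rate_hz, 1.0 / other.sample_rate_hz,
                abs_tol=TIME_TOLERANCE_S,
            )
        )


@dataclass(frozen=True)
class ExpertAnnotation:
    """The intervals one rater selected in one video, in file order."""

    rater_id: str
    video_id: str
    intervals: tuple[TimeInterval, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------


def _infer_rate(times: np.ndarray) -> float:
    gaps = np.diff(times)
    if np.any(gaps <= 0):
        raise SamplingError("frame times must be strictly increasing")
    dt = float(np.median(gaps))
    if np.any(np.abs(gaps - dt) > TIME_TOLERANCE_S):
        raise SamplingError(
            f"non-uniform sampling: gaps deviate from {dt:.6g} s by more than "
            f"{TIME_TOLERANCE_S} s"
        )
    return 1.0 / dt


def _infer_format(path: Path, fmt: PoseFormat | None) -> PoseFormat:
    if fmt is not None:
        if fmt not in ("csv", "coco_json"):
            raise ValueError(f"unknown pose table format {fmt!r}")
        return fmt
    if path.suffix.lower() == ".json":
        return "coco_json"
    return "csv"


def read_pose_table(path: str | Path, format: PoseFormat | None = None) -> PoseSeries:
    """Read a keypoint table into a validated :class:`PoseSeries`.

    The format is inferred from the file suffix unless given explicitly.
    Rows out of time order are rejected, never silently sorted; a frame with
    a keypoint count other than 17 raises :class:`~gmaselect.errors.SchemaError`;
    non-uniform sampling raises :class:`~gmaselect.errors.SamplingError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_pose_csv(path)
    return _read_pose_coco_json(path)


def _numeric_column(df: pd.DataFrame, col: str, *, origin: str) -> np.ndarray:
    # parse with Python's exact float() so values round-trip bit-faithfully
    out = np.empty(len(df), dtype=float)
    for row, raw in enumerate(df[col]):
        try:
            out[row] = float(raw)
        except (TypeError, ValueError):
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"{origin}: line {row + 2}: cannot parse {col}={raw!r}"
            ) from None
    return out


def _read_pose_csv(path: Path) -> PoseSeries:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty pose table") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in _POSE_CSV_COLUMNS if c != "kp_name" and c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: pose table contains no rows")

    times = _numeric_column(df, "time_s", origin=str(path))
    kp_index = _numeric_column(df, "kp_index", origin=str(path))
    x = _numeric_column(df, "x", origin=str(path))
    y = _numeric_column(df, "y", origin=str(path))
    conf = _numeric_column(df, "confidence", origin=str(path))
    if np.any(kp_index != np.round(kp_index)):
        row = int(np.flatnonzero(kp_index != np.round(kp_index))[0])
        raise ParseError(f"{path}: line {row + 2}: kp_index must be an integer")
    kp_index = kp_index.astype(int)
    if np.any((kp_index < 0) | (kp_index >= N_KEYPOINTS)):
        raise SchemaError(f"{path}: kp_index out of range 0..{N_KEYPOINTS - 1}")

    video_ids = df["video_id"].unique()
    if len(video_ids) != 1:
        raise SchemaError(
            f"{path}: a pose table must contain a single video_id, "
            f"found {sorted(video_ids)}"
        )

    return _assemble_series(
        str(video_ids[0]), times, kp_index, x, y, conf, origin=str(path)
    )


def _assemble_series(
    video_id: str,
    times: np.ndarray,
    kp_index: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    conf: np.ndarray,
    *,
    origin: str,
) -> PoseSeries:
    """Group per-keypoint rows into frames and validate the layout."""
    boundaries = np.concatenate(
        ([0], np.flatnonzero(np.diff(times) != 0) + 1, [len(times)])
    )
    frame_times = []
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        if stop - start != N_KEYPOINTS:
            raise SchemaError(
                f"{origin}: frame at t={times[start]:g} s has {stop - start} "
                f"keypoints, expected {N_KEYPOINTS}"
            )
        if not np.array_equal(kp_index[start:stop], np.arange(N_KEYPOINTS)):
            raise SchemaError(
                f"{origin}: frame at t={times[start]:g} s: kp_index must run "
                f"0..{N_KEYPOINTS - 1} in order"
            )
        frame_times.append(times[start])
    frame_times = np.asarray(frame_times)
    if np.any(np.diff(frame_times) < 0):
        bad = int(np.flatnonzero(np.diff(frame_times) < 0)[0])
        line = int(boundaries[bad + 1]) + 2
        raise ParseError(f"{origin}: line {line}: rows out of time order")
    if len(frame_times) < 2:
        raise SchemaError(f"{origin}: a pose series requires at least 2 frames")
    rate = _infer_rate(frame_times)
    n = len(frame_times)
    coords = np.stack([x, y], axis=-1).reshape(n, N_KEYPOINTS, 2)
    confidence = conf.reshape(n, N_KEYPOINTS)
    if np.any((confidence < 0) | (confidence > 1)):
        raise SchemaError(f"{origin}: confidences must lie in [0, 1]")
    if not np.all(np.isfinite(coords)):
        raise SchemaError(f"{origin}: coordinates must be finite")
    return PoseSeries(
        video_id=video_id,
        times=frame_times,
        coords=coords,
        confidence=confidence,
        sample_rate_hz=rate,
    )


def _read_pose_coco_json(path: Path) -> PoseSeries:
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from None
    if isinstance(data, dict):
        data = data.get("frames", data)
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a JSON array of frame objects")
    if len(data) == 0:
        raise SchemaError(f"{path}: pose table contains no frames")

    times_l, kp_l, vid_l = [], [], []
    for i, obj in enumerate(data):
        if not isinstance(obj, dict):
            raise SchemaError(f"{path}: frame {i} is not an object")
        for key in ("video_id", "time_s", "keypoints"):
            if key not in obj:
                raise SchemaError(f"{path}: frame {i} missing key {key!r}")
        kps = obj["keypoints"]
        if not isinstance(kps, list) or len(kps) != 3 * N_KEYPOINTS:
            raise SchemaError(
                f"{path}: frame {i}: keypoints must be a flat array of "
                f"{3 * N_KEYPOINTS} values"
            )
        try:
            times_l.append(float(obj["time_s"]))
            kp_l.append([float(v) for v in kps])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: frame {i}: non-numeric value") from None
        vid_l.append(str(obj["video_id"]))

    if len(set(vid_l)) != 1:
        raise SchemaError(
            f"{path}: a pose table must contain a single video_id, "
            f"found {sorted(set(vid_l))}"
        )
    times = np.asarray(times_l)
    flat = np.asarray(kp_l).reshape(len(data), N_KEYPOINTS, 3)
    frame_times_sorted = np.all(np.diff(times) > 0)
    if not frame_times_sorted:
        raise ParseError(f"{path}: frames out of time order")
    if len(times) < 2:
        raise SchemaError(f"{path}: a pose series requires at least 2 frames")
    confidence = flat[:, :, 2]
    if np.any((confidence < 0) | (confidence > 1)):
        raise SchemaError(f"{path}: confidences must lie in [0, 1]")
    return PoseSeries(
        video_id=vid_l[0],
        times=times,
        coords=flat[:, :, :2].copy(),
        confidence=confidence.copy(),
        sample_rate_hz=_infer_rate(times),
    )


def write_pose_table(
    series: PoseSeries, path: str | Path, format: PoseFormat | None = None
) -> None:
    """Write a pose series so that :func:`read_pose_table` round-trips it.

    Coordinates, confidences and timestamps are written with 6 decimal
    places; the round trip is therefore lossless at that precision.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        n = series.n_frames
        # timestamps keep full precision so uniform-sampling checks survive
        # the round trip at any rate; coordinates use the stated 6 decimals
        df = pd.DataFrame(
            {
                "video_id": np.repeat(series.video_id, n * N_KEYPOINTS),
                "time_s": [
                    f"{t:.12g}" for t in np.repeat(series.times, N_KEYPOINTS)
                ],
                "kp_index": np.tile(np.arange(N_KEYPOINTS), n),
                "kp_name": np.tile(np.asarray(COCO17_KEYPOINT_NAMES), n),
                "x": series.coords[:, :, 0].ravel(),
                "y": series.coords[:, :, 1].ravel(),
                "confidence": series.confidence.ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")
    else:
        frames = []
        for i in range(series.n_frames):
            flat = np.column_stack(
                (series.coords[i], series.confidence[i][:, None])
            ).ravel()
            frames.append(
                {
                    "video_id": series.video_id,
                    "time_s": float(series.times[i]),
                    "keypoints": [round(float(v), 6) for v in flat],
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(frames, fh)


def resample(series: PoseSeries, target_hz: float) -> PoseSeries:
    """Decimate a pose series to ``target_hz`` by keeping every
    ``sample_rate_hz / target_hz``-th frame, starting at the first.

    Only integer decimation is supported (the ratio must be an integer
    within 1e-9); upsampling raises :class:`~gmaselect.errors.ResamplingError`.
    Timestamps of the retained frames are preserved.
    """
    if target_hz <= 0:
        raise ResamplingError("target rate must be positive")
    if target_hz > series.sample_rate_hz * (1 + 1e-12):
        raise ResamplingError(
            f"upsampling from {series.sample_rate_hz} Hz to {target_hz} Hz "
            "is not supported"
        )
    ratio = series.sample_rate_hz / target_hz
    step = round(ratio)
    if abs(ratio - step) > 1e-9:
        raise ResamplingError(
            f"decimation ratio {ratio:g} is not an integer; "
            "only integer decimation is supported"
        )
    if step == 1:
        return series
    if (series.n_frames - 1) // step + 1 < 2:
        raise ResamplingError(
            f"decimating {series.n_frames} frames by {step} leaves fewer "
            "than 2 frames"
        )
    return PoseSeries(
        video_id=series.video_id,
        times=series.times[::step].copy(),
        coords=series.coords[::step].copy(),
        confidence=series.confidence[::step].copy(),
        sample_rate_hz=target_hz,
        frame_width_px=series.frame_width_px,
        frame_height_px=series.frame_height_px,
    )


# ---------------------------------------------------------------------------
# expert annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> list[ExpertAnnotation]:
    """Read an annotation CSV into one :class:`ExpertAnnotation` per
    ``(rater_id, video_id)`` pair, intervals in file order.

    Raises :class:`~gmaselect.errors.AnnotationError` for an interval with
    ``end <= start`` or a duplicate ``(rater, video, start)`` row. An empty
    file yields an empty collection.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return []
    start = _numeric_column(df, "start_s", origin=str(path))
    end = _numeric_column(df, "end_s", origin=str(path))
    bad = end <= start
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise AnnotationError(
            f"{path}: line {row + 2}: interval end ({end[row]:g}) must exceed "
            f"start ({start[row]:g})"
        )
    key = list(zip(df["rater_id"], df["video_id"], start))
    seen: set[tuple[str, str, float]] = set()
    for row, k in enumerate(key):
        if k in seen:
            raise AnnotationError(
                f"{path}: line {row + 2}: duplicate (rater_id, video_id, "
                f"start_s) = {k}"
            )
        seen.add(k)
    grouped: dict[tuple[str, str], list[TimeInterval]] = {}
    for row in range(len(df)):
        pair = (str(df["rater_id"].iloc[row]), str(df["video_id"].iloc[row]))
        grouped.setdefault(pair, []).append(TimeInterval(start[row], end[row]))
    return [
        ExpertAnnotation(rater_id=r, video_id=v, intervals=tuple(ivs))
        for (r, v), ivs in grouped.items()
    ]


def write_annotations(annotations: Sequence[ExpertAnnotation], path: str | Path) -> None:
    """Write annotations in the CSV dialect accepted by :func:`read_annotations`."""
    rows = [
        {
            "rater_id": ann.rater_id,
            "video_id": ann.video_id,
            # shortest round-trip formatting keeps the file bit-faithful
            "start_s": repr(float(iv.start_s)),
            "end_s": repr(float(iv.end_s)),
        }
        for ann in annotations
        for iv in ann.intervals
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, index=False)
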