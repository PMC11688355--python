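"""Selection of the highest-motion fixed-duration sequences.

The score of a candidate window starting at motion-sample index ``j`` is the
summing-window function

    G(j) = sum_{i=j}^{j+W-1} S_i

with ``W = round(window_s * sample_rate_hz)`` motion samples, i.e. a window
of ``window_s`` seconds covers exactly ``W`` inter-frame displacements
(half-open in sample space). The best sequence starts at the smallest ``j``
attaining ``max_j G(j)``; ties always break to the minimum start index.

Multiple sequences are selected greedily: pick the argmax window, discard all
windows overlapping it in sample-index space, repeat. A ``free`` mode that
permits overlaps is available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, WindowTooLongError
from .intervals import TimeInterval
from .motion import MotionSeries

OverlapPolicy = Literal["disjoint", "free"]

_SELECTION_CSV_COLUMNS = ["video_id", "rank", "start_s", "end_s", "score"]


@dataclass(eq=False)
class SelectionResult:
    """Ranked selected intervals and their window scores for one video.

    Intervals are ordered by descending score, ties by ascending start time;
    ``scores`` are window sums in pixel·samples. ``k_returned`` may fall
    short of ``k_requested`` when disjoint candidates run out.
    """

    video_id: str
    intervals: tuple[TimeInterval, ...]
    scores: tuple[float, ...]
    window_s: float
    k_requested: int
    k_returned: int

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.scores):
            raise SchemaError("intervals and scores must have equal length")
        if self.k_returned != len(self.intervals):
            raise SchemaError("k_returned must equal the number of intervals")
        if self.k_returned > self.k_requested:
            raise SchemaError("k_returned cannot exceed k_requested")
        diffs = np.diff(np.asarray(self.scores, dtype=float))
        if diffs.size and np.any(diffs > 1e-9):
            raise SchemaError("scores must be non-increasing")


def _window_samples(motion: MotionSeries, window_s: float) -> int:
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    w = int(round(window_s * motion.sample_rate_hz))
    if w < 1:
        raise ValueError(
            f"window of {window_s} s spans no motion sample at "
            f"{motion.sample_rate_hz} Hz"
        )
    # warn whenever the requested duration is not a whole number of samples
    if abs(window_s * motion.sample_rate_hz - w) > 1e-9:
        warnings.warn(
            f"window of {window_s} s rounded to {w} samples "
            f"({w / motion.sample_rate_hz:g} s) at {motion.sample_rate_hz} Hz",
            stacklevel=3,
        )
    if w > len(motion):
        raise WindowTooLongError(
            f"window of {w} samples exceeds motion series length {len(motion)}"
        )
    return w


def _score_array(values: np.ndarray, w: int) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return csum[w:] - csum[:-w]


def window_scores(
    motion: MotionSeries, window_s: float
) -> list[tuple[int, float]]:
    """Score every candidate window: ``[(start_index, G(start_index)), ...]``.

    Computed in O(n) with a running sum over all starts ``0..len - W``.
    """
    w = _window_samples(motion, window_s)
    scores = _score_array(motion.values, w)
    return [(int(j), float(s)) for j, s in enumerate(scores)]


def _interval_at(motion: MotionSeries, j: int, w: int) -> TimeInterval:
    start = motion.t0_s + j / motion.sample_rate_hz
    return TimeInterval(start, start + w / motion.sample_rate_hz)


def select_best(motion: MotionSeries, window_s: float) -> TimeInterval:
    """The single highest-motion window, ties broken to the earliest start."""
    w = _window_samples(motion, window_s)
    scores = _score_array(motion.values, w)
    j = int(np.argmax(scores))  # argmax returns the first (minimum) index
    return _interval_at(motion, j, w)


def select_top_k(
    motion: MotionSeries,
    window_s: float,
    k: int,
    overlap: OverlapPolicy = "disjoint",
) -> SelectionResult:
    """Select the ``k`` highest-motion windows.

    ``disjoint`` (default): greedy — take the argmax window (ties to the
    minimum start index), remove every window overlapping it in sample-index
    space, repeat until ``k`` windows are found or candidates are exhausted.
    ``free``: the ``k`` largest scores regardless of overlap, ties to the
    minimum index.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if overlap not in ("disjoint", "free"):
        raise ValueError(f"unknown overlap policy {overlap!r}")
    w = _window_samples(motion, window_s)
    scores = _score_array(motion.values, w)
    n = scores.shape[0]

    picked: list[int] = []
    if overlap == "free":
        order = np.lexsort((np.arange(n), -scores))
        picked = [int(j) for j in order[:k]]
    else:
        available = np.ones(n, dtype=bool)
        masked = scores.copy()
        for _ in range(k):
            if not available.any():
                break
            masked = np.where(available, scores, -np.inf)
            j = int(np.argmax(masked))
            picked.append(j)
            lo = max(0, j - w + 1)
            available[lo : j + w] = False

    intervals = tuple(_interval_at(motion, j, w) for j in picked)
    return SelectionResult(
        video_id=motion.video_id,
        intervals=intervals,
        scores=tuple(float(scores[j]) for j in picked),
        window_s=w / motion.sample_rate_hz,
        k_requested=k,
        k_returned=len(picked),
    )


def write_selection_csv(
    results: Sequence[SelectionResult], path: str | Path
) -> None:
    """Export selections with header ``video_id,rank,start_s,end_s,score``."""
    rows = [
        {
            "video_id": res.video_id,
            "rank": rank,
            # shortest round-trip formatting: the file is bit-faithful
            "start_s": repr(float(iv.start_s)),
            "end_s": repr(float(iv.end_s)),
            "score": repr(float(score)),
        }
        for res in results
        for rank, (iv, score) in enumerate(zip(res.intervals, res.scores), start=1)
    ]
    pd.DataFrame(rows, columns=_SELECTION_CSV_COLUMNS).to_csv(path, index=False)


def read_selection_csv(path: str | Path) -> list[SelectionResult]:
    """Read selections written by :func:`write_selection_csv`, one result
    per video in file order."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SELECTION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    results = []
    for video_id, group in df.groupby("video_id", sort=False):
        ranks = group["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(group) + 1)):
            raise SchemaError(
                f"{path}: ranks for video {video_id!r} must run 1..k in order"
            )
        intervals = tuple(
            TimeInterval(float(s), float(e))
            for s, e in zip(group["start_s"], group["end_s"])
        )
        results.append(
            SelectionResult(
                video_id=str(video_id),
                intervals=intervals,
                scores=tuple(float(v) for v in group["score"]),
                window_s=intervals[0].duration_s,
                k_requested=len(intervals),
                k_returned=len(intervals),
            )
        )
    return results
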