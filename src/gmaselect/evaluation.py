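"""Agreement between automatic selections and expert interval annotations.

For a software-selected interval ``x`` and an expert's interval ``y``, the
temporal intersection is ``I(x, y) = max(0, min(ends) - max(starts))`` and
the dice similarity is ``DS = 2 I / (|x| + |y|)``. Each software interval is
matched, independently per expert, to the expert interval maximising the
intersection (ties to the lowest 1-based index); the maximum dice similarity
(MDS) of a software interval is the best matched DS over all experts. The
agreement of a whole selection run at threshold ``tau`` is

    Precision(tau) = #{sequences with MDS > tau} / (total sequences)

with a *strict* inequality, so even a perfect selector scores 0 at
``tau = 1.0`` — a documented consequence of the definition, not a defect.

The same machinery yields inter-rater agreement (each expert's intervals
scored against the remaining experts) and leave-one-expert-out software
precision curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .intervals import TimeInterval
from .pose_io import ExpertAnnotation
from .selector import SelectionResult

#: Default threshold grid: 0.00, 0.01, ..., 1.00.
DEFAULT_TAU_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class MatchedPair:
    """A software interval matched to one expert's best-overlapping interval."""

    software_interval: TimeInterval
    expert_interval: TimeInterval
    expert_index: int  # 1-based index into the expert's interval list
    intersection_s: float
    dice: float


@dataclass(eq=False)
class PrecisionCurve:
    """Precision evaluated on a grid of dice thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.thresholds.shape != self.precision.shape:
            raise EvaluationError("thresholds and precision must align")

    def at(self, tau: float) -> float:
        """Precision at the grid point closest to ``tau`` (exact match expected)."""
        i = int(np.argmin(np.abs(self.thresholds - tau)))
        return float(self.precision[i])


@dataclass(eq=False)
class EvaluationReport:
    """All agreement metrics for one selection run.

    ``per_sequence_mds`` has one row per (video, rank) with the interval and
    its MDS over all experts; curve collections are keyed by rater id.
    """

    per_sequence_mds: pd.DataFrame
    software_vs_experts: PrecisionCurve
    leave_one_out: dict[str, PrecisionCurve]
    inter_rater: dict[str, PrecisionCurve]
    averages: dict[str, PrecisionCurve] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def curve(c: PrecisionCurve) -> dict:
            return {
                "thresholds": c.thresholds.tolist(),
                "precision": c.precision.tolist(),
                "n_sequences": c.n_sequences,
            }

        return {
            "per_sequence_mds": self.per_sequence_mds.to_dict(orient="records"),
            "software_vs_experts": curve(self.software_vs_experts),
            "leave_one_out": {k: curve(v) for k, v in self.leave_one_out.items()},
            "inter_rater": {k: curve(v) for k, v in self.inter_rater.items()},
            "averages": {k: curve(v) for k, v in self.averages.items()},
        }


# ---------------------------------------------------------------------------
# elementary interval metrics
# ---------------------------------------------------------------------------


def interval_intersection(x: TimeInterval, y: TimeInterval) -> float:
    """Overlap in seconds: ``max(0, min(ends) - max(starts))``."""
    return max(0.0, min(x.end_s, y.end_s) - max(x.start_s, y.start_s))


def dice_similarity(x: TimeInterval, y: TimeInterval) -> float:
    """``2 I(x, y) / (|x| + |y|)``: 1 for identical intervals, 0 if disjoint."""
    return 2.0 * interval_intersection(x, y) / (x.duration_s + y.duration_s)


def match_expert_sequence(x: TimeInterval, expert: ExpertAnnotation) -> MatchedPair:
    """Match ``x`` to the expert interval with the largest intersection.

    Ties (including the all-zero case of a fully disjoint ``x``) resolve to
    the minimum 1-based index. Matching is independent per software
    sequence: the same expert interval may be matched repeatedly.
    """
    if not expert.intervals:
        raise EvaluationError(
            f"expert {expert.rater_id!r} has no intervals for video "
            f"{expert.video_id!r}"
        )
    overlaps = [interval_intersection(x, y) for y in expert.intervals]
    c = int(np.argmax(overlaps))  # first maximum = lowest index
    y = expert.intervals[c]
    return MatchedPair(
        software_interval=x,
        expert_interval=y,
        expert_index=c + 1,
        intersection_s=overlaps[c],
        dice=dice_similarity(x, y),
    )


def max_dice_similarity(
    x: TimeInterval, experts: Sequence[ExpertAnnotation]
) -> float:
    """Best matched dice similarity of ``x`` over a collection of experts."""
    if not experts:
        raise EvaluationError("at least one expert annotation is required")
    return max(match_expert_sequence(x, e).dice for e in experts)


# ---------------------------------------------------------------------------
# precision over selection runs
# ---------------------------------------------------------------------------


def _experts_by_video(
    experts: Sequence[ExpertAnnotation],
) -> dict[str, list[ExpertAnnotation]]:
    grouped: dict[str, list[ExpertAnnotation]] = {}
    for e in experts:
        grouped.setdefault(e.video_id, []).append(e)
    return grouped


def _mds_values(
    selections: Sequence[SelectionResult],
    experts: Sequence[ExpertAnnotation],
) -> list[float]:
    """MDS of every selected sequence across all videos, in selection order."""
    by_video = _experts_by_video(experts)
    missing = sorted(
        {s.video_id for s in selections if s.video_id not in by_video}
    )
    if missing:
        raise EvaluationError(
            f"no expert annotations for selected videos: {missing}"
        )
    values = []
    for sel in selections:
        if sel.k_returned < sel.k_requested:
            warnings.warn(
                f"video {sel.video_id!r}: only {sel.k_returned} of "
                f"{sel.k_requested} sequences selected; the precision "
                "denominator uses the returned count",
                stacklevel=3,
            )
        for x in sel.intervals:
            values.append(max_dice_similarity(x, by_video[sel.video_id]))
    return values


def precision(
    selections: Sequence[SelectionResult],
    experts: Sequence[ExpertAnnotation],
    tau: float,
) -> float:
    """Fraction of selected sequences whose MDS strictly exceeds ``tau``.

    The denominator is the total number of sequences actually returned
    across videos.
    """
    mds = _mds_values(selections, experts)
    if not mds:
        raise EvaluationError("no selected sequences to evaluate")
    return sum(v > tau for v in mds) / len(mds)


def _curve_from_mds(mds: Sequence[float], tau_grid: np.ndarray) -> PrecisionCurve:
    mds_arr = np.asarray(mds, dtype=float)
    grid = np.asarray(tau_grid, dtype=float)
    prec = (mds_arr[None, :] > grid[:, None]).mean(axis=1)
    return PrecisionCurve(thresholds=grid, precision=prec, n_sequences=len(mds))


def precision_curve(
    selections: Sequence[SelectionResult],
    experts: Sequence[ExpertAnnotation],
    tau_grid: np.ndarray = DEFAULT_TAU_GRID,
) -> PrecisionCurve:
    """Precision evaluated at every threshold of ``tau_grid``."""
    mds = _mds_values(selections, experts)
    if not mds:
        raise EvaluationError("no selected sequences to evaluate")
    return _curve_from_mds(mds, tau_grid)


def leave_one_out_precision(
    selections: Sequence[SelectionResult],
    experts: Sequence[ExpertAnnotation],
    tau_grid: np.ndarray = DEFAULT_TAU_GRID,
) -> dict[str, PrecisionCurve]:
    """Software precision excluding one expert at a time.

    Returns one curve per excluded rater: the MDS of each selection is taken
    over the remaining raters only.
    """
    raters = _rater_ids(experts)
    if len(raters) < 2:
        raise EvaluationError("leave-one-out requires at least 2 experts")
    return {
        r: precision_curve(
            selections, [e for e in experts if e.rater_id != r], tau_grid
        )
        for r in raters
    }


def inter_rater_precision(
    experts: Sequence[ExpertAnnotation],
    tau_grid: np.ndarray = DEFAULT_TAU_GRID,
    ns_per_video: int | None = None,
) -> dict[str, PrecisionCurve]:
    """Each expert's intervals scored against the remaining experts.

    Expert ``e``'s intervals play the role of the software selection; the
    denominator counts ``e``'s sequences across videos. ``ns_per_video``, if
    given, triggers a warning when an expert annotated a different number of
    intervals in some video.
    """
    raters = _rater_ids(experts)
    if len(raters) < 2:
        raise EvaluationError("inter-rater precision requires at least 2 experts")
    curves: dict[str, PrecisionCurve] = {}
    for r in raters:
        own = [e for e in experts if e.rater_id == r]
        others = [e for e in experts if e.rater_id != r]
        if ns_per_video is not None:
            for e in own:
                if len(e.intervals) != ns_per_video:
                    warnings.warn(
                        f"rater {r!r} annotated {len(e.intervals)} intervals "
                        f"in video {e.video_id!r}, expected {ns_per_video}",
                        stacklevel=2,
                    )
        pseudo = [
            SelectionResult(
                video_id=e.video_id,
                intervals=e.intervals,
                scores=tuple(0.0 for _ in e.intervals),
                window_s=e.intervals[0].duration_s if e.intervals else 0.0,
                k_requested=len(e.intervals),
                k_returned=len(e.intervals),
            )
            for e in own
            if e.intervals
        ]
        curves[r] = precision_curve(pseudo, others, tau_grid)
    return curves


def _rater_ids(experts: Sequence[ExpertAnnotation]) -> list[str]:
    seen: dict[str, None] = {}
    for e in experts:
        seen.setdefault(e.rater_id, None)
    return list(seen)


def average_curves(
    curves: Sequence[PrecisionCurve],
) -> tuple[PrecisionCurve, PrecisionCurve]:
    """Pointwise mean and population standard deviation of curves sharing a grid."""
    if not curves:
        raise EvaluationError("cannot average an empty set of curves")
    grid = curves[0].thresholds
    for c in curves[1:]:
        if not np.array_equal(c.thresholds, grid):
            raise EvaluationError("curves must share the same threshold grid")
    stack = np.stack([c.precision for c in curves])
    n_total = int(sum(c.n_sequences for c in curves))
    mean = PrecisionCurve(grid, stack.mean(axis=0), n_total)
    std = PrecisionCurve(grid, stack.std(axis=0), n_total)
    return mean, std


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def evaluate(
    selections: Sequence[SelectionResult],
    experts: Sequence[ExpertAnnotation],
    tau_grid: np.ndarray = DEFAULT_TAU_GRID,
) -> EvaluationReport:
    """Compute the complete agreement report for a selection run."""
    by_video = _experts_by_video(experts)
    rows = []
    for sel in selections:
        if sel.video_id not in by_video:
            raise EvaluationError(
                f"no expert annotations for selected video {sel.video_id!r}"
            )
        for rank, x in enumerate(sel.intervals, start=1):
            rows.append(
                {
                    "video_id": sel.video_id,
                    "rank": rank,
                    "start_s": x.start_s,
                    "end_s": x.end_s,
                    "mds": max_dice_similarity(x, by_video[sel.video_id]),
                }
            )
    per_sequence = pd.DataFrame(
        rows, columns=["video_id", "rank", "start_s", "end_s", "mds"]
    )
    full_curve = precision_curve(selections, experts, tau_grid)
    n_raters = len(_rater_ids(experts))
    loo = (
        leave_one_out_precision(selections, experts, tau_grid)
        if n_raters >= 2
        else {}
    )
    inter = (
        inter_rater_precision(experts, tau_grid) if n_raters >= 2 else {}
    )
    averages: dict[str, PrecisionCurve] = {}
    if loo:
        m, s = average_curves(list(loo.values()))
        averages["software_vs_experts_mean"] = m
        averages["software_vs_experts_std"] = s
    if inter:
        m, s = average_curves(list(inter.values()))
        averages["inter_rater_mean"] = m
        averages["inter_rater_std"] = s
    return EvaluationReport(
        per_sequence_mds=per_sequence,
        software_vs_experts=full_curve,
        leave_one_out=loo,
        inter_rater=inter,
        averages=averages,
    )


def write_report_json(report: EvaluationReport, path: str | Path, **metadata) -> None:
    """Serialise a report (plus optional run metadata) to JSON."""
    payload = report.to_dict()
    if metadata:
        payload["metadata"] = metadata
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def write_curves_csv(
    curves: Mapping[str, PrecisionCurve], path: str | Path
) -> None:
    """Export curves in long form: ``curve,tau,precision,n_sequences``."""
    rows = [
        {
            "curve": name,
            "tau": float(t),
            "precision": float(p),
            "n_sequences": c.n_sequences,
        }
        for name, c in curves.items()
        for t, p in zip(c.thresholds, c.precision)
    ]
    pd.DataFrame(rows, columns=["curve", "tau", "precision", "n_sequences"]).to_csv(
        path, index=False
    )
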