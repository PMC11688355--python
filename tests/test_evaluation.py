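"""Interval agreement metrics: intersection, dice, MDS, precision curves."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmaselect import (
    EvaluationError,
    ExpertAnnotation,
    SelectionResult,
    TimeInterval,
    average_curves,
    dice_similarity,
    evaluate,
    inter_rater_precision,
    interval_intersection,
    leave_one_out_precision,
    match_expert_sequence,
    max_dice_similarity,
    precision,
    precision_curve,
)

import oracles


def iv(a, b):
    return TimeInterval(float(a), float(b))


def ann(rater, video, pairs):
    return ExpertAnnotation(
        rater_id=rater, video_id=video, intervals=tuple(iv(a, b) for a, b in pairs)
    )


def sel(video, pairs):
    intervals = tuple(iv(a, b) for a, b in pairs)
    return SelectionResult(
        video_id=video,
        intervals=intervals,
        scores=tuple(0.0 for _ in intervals),
        window_s=intervals[0].duration_s,
        k_requested=len(intervals),
        k_returned=len(intervals),
    )


intervals_strategy = st.tuples(
    st.floats(min_value=0, max_value=3000),
    st.floats(min_value=1, max_value=300),
).map(lambda t: iv(t[0], t[0] + t[1]))


class TestIntersection:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((0, 60), (0, 60), 60.0),
            ((0, 60), (60, 120), 0.0),   # touching half-open intervals
            ((0, 60), (30, 90), 30.0),
            ((10, 20), (0, 100), 10.0),
        ],
    )
    def test_examples(self, x, y, expected):
        assert interval_intersection(iv(*x), iv(*y)) == expected

    @given(intervals_strategy, intervals_strategy)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bounds_and_symmetry(self, x, y):
        i = interval_intersection(x, y)
        assert 0.0 <= i <= min(x.duration_s, y.duration_s) + 1e-12
        assert i == interval_intersection(y, x)
        assert interval_intersection(x, x) == pytest.approx(x.duration_s)


class TestDice:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((0, 60), (0, 60), 1.0),
            ((0, 60), (120, 180), 0.0),
            ((0, 60), (30, 90), 0.5),
        ],
    )
    def test_examples(self, x, y, expected):
        assert dice_similarity(iv(*x), iv(*y)) == pytest.approx(expected)

    @given(intervals_strategy, intervals_strategy)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_axioms(self, x, y):
        d = dice_similarity(x, y)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(dice_similarity(y, x))
        assert (d == 0.0) == (interval_intersection(x, y) == 0.0)
        if x == y:
            assert d == pytest.approx(1.0)
        assert dice_similarity(x, x) == pytest.approx(1.0)

    def test_one_iff_identical(self):
        # same midpoint overlap but unequal lengths never reaches 1
        assert dice_similarity(iv(0, 60), iv(0, 90)) < 1.0


class TestMatching:
    def test_single_overlapping_candidate(self):
        expert = ann("e1", "v", [(0, 60), (90, 150), (400, 460)])
        m = match_expert_sequence(iv(100, 160), expert)
        assert m.expert_index == 2  # 1-based
        assert m.intersection_s == 50.0
        assert m.expert_interval == iv(90, 150)

    def test_fully_disjoint_ties_to_first(self):
        expert = ann("e1", "v", [(0, 60), (90, 150)])
        m = match_expert_sequence(iv(1000, 1060), expert)
        assert m.expert_index == 1
        assert m.intersection_s == 0.0
        assert m.dice == 0.0

    def test_equal_overlap_ties_to_lower_index(self):
        expert = ann("e1", "v", [(0, 60), (100, 160)])
        # x overlaps both by exactly 10 s
        m = match_expert_sequence(iv(50, 110), expert)
        assert m.expert_index == 1

    def test_empty_annotation_is_error(self):
        with pytest.raises(EvaluationError):
            match_expert_sequence(iv(0, 60), ann("e1", "v", []))


class TestMds:
    def test_identical_interval_scores_one(self):
        assert max_dice_similarity(iv(0, 60), [ann("e1", "v", [(0, 60)])]) == 1.0

    def test_all_disjoint_scores_zero(self):
        experts = [ann(f"e{i}", "v", [(1000 + 100 * i, 1060 + 100 * i)]) for i in range(4)]
        assert max_dice_similarity(iv(0, 60), experts) == 0.0

    def test_maximum_over_experts(self):
        # per-expert dice values 0.2, 0.7, 0.4, 0.0 for x = [0, 60)
        def interval_with_dice(d):
            # same 60 s length, overlap o gives dice o/60
            o = 60.0 * d
            return (60.0 - o, 120.0 - o)

        experts = [
            ann("e1", "v", [interval_with_dice(0.2)]),
            ann("e2", "v", [interval_with_dice(0.7)]),
            ann("e3", "v", [interval_with_dice(0.4)]),
            ann("e4", "v", [(500, 560)]),
        ]
        assert max_dice_similarity(iv(0, 60), experts) == pytest.approx(0.7)

    def test_empty_expert_collection_is_error(self):
        with pytest.raises(EvaluationError):
            max_dice_similarity(iv(0, 60), [])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_superset_dominance(self, seed):
        rng = np.random.default_rng(seed)
        x = iv(float(rng.uniform(0, 440)), float(rng.uniform(450, 500)))
        experts = [
            ann(f"e{i}", "v",
                [(s, s + 60) for s in rng.uniform(0, 500, size=3)])
            for i in range(4)
        ]
        full = max_dice_similarity(x, experts)
        for i in range(4):
            subset = experts[:i] + experts[i + 1:]
            assert full >= max_dice_similarity(x, subset) - 1e-12


class TestPrecision:
    def test_perfect_agreement(self):
        experts = [ann("e1", "v1", [(0, 60), (200, 260)])]
        sels = [sel("v1", [(0, 60), (200, 260)])]
        assert precision(sels, experts, 0.5) == 1.0

    def test_no_overlap_is_zero_even_at_tau_zero(self):
        experts = [ann("e1", "v1", [(1000, 1060)])]
        sels = [sel("v1", [(0, 60)])]
        assert precision(sels, experts, 0.0) == 0.0  # MDS = 0 is not > 0

    def test_counted_exceedances_26_of_30(self):
        """6 videos x 5 sequences; 26 built to exceed tau=0.5, 4 not."""
        experts, sels, built = [], [], 0
        for v in range(6):
            video = f"v{v}"
            experts.append(ann("e1", video, [(i * 200, i * 200 + 60) for i in range(5)]))
            pairs = []
            for i in range(5):
                base = i * 200
                if built < 26:
                    pairs.append((base + 20, base + 80))   # overlap 40 -> DS 2/3
                    built += 1
                else:
                    pairs.append((base + 50, base + 110))  # overlap 10 -> DS 1/6
            sels.append(sel(video, pairs))
        assert precision(sels, experts, 0.5) == pytest.approx(26 / 30)

    def test_missing_video_annotations_is_error(self):
        with pytest.raises(EvaluationError, match="v2"):
            precision([sel("v2", [(0, 60)])], [ann("e1", "v1", [(0, 60)])], 0.5)

    def test_monotone_in_tau(self, rng):
        experts = [
            ann(f"e{i}", "v1", [(s, s + 60) for s in rng.uniform(0, 2000, size=5)])
            for i in range(4)
        ]
        sels = [sel("v1", [(s, s + 60) for s in rng.uniform(0, 2000, size=5)])]
        taus = np.linspace(0, 1, 21)
        values = [precision(sels, experts, t) for t in taus]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestPrecisionCurve:
    def test_perfect_selector_is_flat_one_until_tau_one(self):
        experts = [ann("e1", "v1", [(0, 60)])]
        sels = [sel("v1", [(0, 60)])]
        curve = precision_curve(sels, experts)
        assert np.all(curve.precision[:-1] == 1.0)
        assert curve.precision[-1] == 0.0  # strict inequality at tau = 1

    def test_disjoint_selector_is_flat_zero(self):
        experts = [ann("e1", "v1", [(1000, 1060)])]
        sels = [sel("v1", [(0, 60)])]
        assert np.all(precision_curve(sels, experts).precision == 0.0)

    def test_matches_tabulated_step_function(self, rng):
        experts = [
            ann(f"e{i}", "v1", [(s, s + 60) for s in rng.uniform(0, 2000, size=5)])
            for i in range(3)
        ]
        sels = [sel("v1", [(s, s + 60) for s in rng.uniform(0, 2000, size=6)])]
        curve = precision_curve(sels, experts)
        expert_lists = [
            [(y.start_s, y.end_s) for y in e.intervals] for e in experts
        ]
        mds = [
            oracles.brute_mds((x.start_s, x.end_s), expert_lists)
            for x in sels[0].intervals
        ]
        expected = [oracles.brute_precision(mds, t) for t in curve.thresholds]
        assert curve.precision == pytest.approx(expected)
        assert curve.n_sequences == 6


class TestLeaveOneOut:
    def test_identical_experts_leave_curve_unchanged(self):
        experts = [ann(f"e{i}", "v1", [(0, 60), (200, 260)]) for i in range(4)]
        sels = [sel("v1", [(10, 70), (210, 270)])]
        full = precision_curve(sels, experts)
        curves = leave_one_out_precision(sels, experts)
        assert set(curves) == {"e0", "e1", "e2", "e3"}
        for c in curves.values():
            assert c.precision == pytest.approx(full.precision)

    def test_excluding_irrelevant_expert_changes_nothing(self):
        relevant = [ann(f"e{i}", "v1", [(0, 60)]) for i in range(3)]
        outlier = ann("far", "v1", [(3000, 3060)])
        sels = [sel("v1", [(5, 65)])]
        curves = leave_one_out_precision(sels, relevant + [outlier])
        full_without = precision_curve(sels, relevant)
        assert curves["far"].precision == pytest.approx(full_without.precision)

    def test_matches_per_subset_recomputation(self, rng):
        experts = [
            ann(f"e{i}", "v1", [(s, s + 60) for s in rng.uniform(0, 2000, size=4)])
            for i in range(4)
        ]
        sels = [sel("v1", [(s, s + 60) for s in rng.uniform(0, 2000, size=5)])]
        curves = leave_one_out_precision(sels, experts)
        for excluded in curves:
            subset = [e for e in experts if e.rater_id != excluded]
            expected = precision_curve(sels, subset)
            assert curves[excluded].precision == pytest.approx(expected.precision)

    def test_requires_two_experts(self):
        with pytest.raises(EvaluationError):
            leave_one_out_precision(
                [sel("v1", [(0, 60)])], [ann("e1", "v1", [(0, 60)])]
            )


class TestInterRater:
    def test_two_identical_experts_agree_fully(self):
        experts = [ann(f"e{i}", "v1", [(0, 60), (100, 160)]) for i in range(2)]
        curves = inter_rater_precision(experts)
        for c in curves.values():
            assert np.all(c.precision[:-1] == 1.0)
            assert c.n_sequences == 2

    def test_disjoint_experts_score_zero(self):
        experts = [
            ann("e1", "v1", [(0, 60)]),
            ann("e2", "v1", [(1000, 1060)]),
        ]
        curves = inter_rater_precision(experts)
        for c in curves.values():
            assert np.all(c.precision == 0.0)

    def test_matches_brute_force_oracle(self, rng):
        experts = [
            ann(f"e{i}", "v1",
                [(s, s + 60) for s in 100 + 300 * np.arange(4) + rng.normal(0, 5, 4)])
            for i in range(4)
        ]
        curves = inter_rater_precision(experts)
        for r, curve in curves.items():
            own = next(e for e in experts if e.rater_id == r)
            other_lists = [
                [(y.start_s, y.end_s) for y in e.intervals]
                for e in experts
                if e.rater_id != r
            ]
            mds = [
                oracles.brute_mds((x.start_s, x.end_s), other_lists)
                for x in own.intervals
            ]
            expected = [oracles.brute_precision(mds, t) for t in curve.thresholds]
            assert curve.precision == pytest.approx(expected)


class TestAverageCurves:
    def test_identical_curves(self):
        experts = [ann(f"e{i}", "v1", [(0, 60)]) for i in range(2)]
        sels = [sel("v1", [(0, 60)])]
        c = precision_curve(sels, experts)
        mean, std = average_curves([c, c, c])
        assert mean.precision == pytest.approx(c.precision)
        assert std.precision == pytest.approx(np.zeros_like(c.precision))

    def test_zero_one_curves(self):
        grid = np.linspace(0, 1, 11)
        from gmaselect import PrecisionCurve

        c0 = PrecisionCurve(grid, np.zeros(11), 5)
        c1 = PrecisionCurve(grid, np.ones(11), 5)
        mean, std = average_curves([c0, c1])
        assert np.all(mean.precision == 0.5)
        assert np.all(std.precision == 0.5)

    def test_mismatched_grids_rejected(self):
        from gmaselect import PrecisionCurve

        c0 = PrecisionCurve(np.linspace(0, 1, 11), np.zeros(11), 1)
        c1 = PrecisionCurve(np.linspace(0, 1, 21), np.zeros(21), 1)
        with pytest.raises(EvaluationError):
            average_curves([c0, c1])


class TestFullReport:
    def test_pipeline_matches_exhaustive_recomputation(self, rng):
        """Every reported MDS and precision equals an independent loop."""
        videos = [f"v{i}" for i in range(4)]
        experts = [
            ann(f"e{r}", v, [(s, s + 60) for s in rng.uniform(0, 1500, size=4)])
            for r in range(4)
            for v in videos
        ]
        sels = [
            sel(v, [(s, s + 60) for s in rng.uniform(0, 1500, size=3)])
            for v in videos
        ]
        report = evaluate(sels, experts)
        assert len(report.per_sequence_mds) == 12
        for _, row in report.per_sequence_mds.iterrows():
            expert_lists = [
                [(y.start_s, y.end_s) for y in e.intervals]
                for e in experts
                if e.video_id == row.video_id
            ]
            expected = oracles.brute_mds((row.start_s, row.end_s), expert_lists)
            assert row.mds == pytest.approx(expected)
        # averages are pointwise means of the stored component curves
        loo_stack = np.stack([c.precision for c in report.leave_one_out.values()])
        assert report.averages["software_vs_experts_mean"].precision == pytest.approx(
            loo_stack.mean(axis=0)
        )
        inter_stack = np.stack([c.precision for c in report.inter_rater.values()])
        assert report.averages["inter_rater_mean"].precision == pytest.approx(
            inter_stack.mean(axis=0)
        )
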