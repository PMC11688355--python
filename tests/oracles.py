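"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's running-sum / vectorised code paths:
every window is summed directly, every match enumerated with plain loops.
"""

from __future__ import annotations

import numpy as np


def brute_window_scores(values: np.ndarray, w: int) -> list[float]:
    """Sum every window directly (O(n*W))."""
    return [float(np.sum(values[j : j + w])) for j in range(len(values) - w + 1)]


def brute_select_best(values: np.ndarray, w: int) -> int:
    """Exhaustive argmax with minimum-index tie-breaking."""
    scores = brute_window_scores(values, w)
    best, best_j = scores[0], 0
    for j, s in enumerate(scores):
        if s > best:
            best, best_j = s, j
    return best_j


def brute_greedy_disjoint(values: np.ndarray, w: int, k: int) -> list[int]:
    """Greedy exhaustive top-k with the same min-index tie rule."""
    scores = brute_window_scores(values, w)
    candidates = list(range(len(scores)))
    picked: list[int] = []
    while candidates and len(picked) < k:
        best_j = candidates[0]
        for j in candidates:
            if scores[j] > scores[best_j]:
                best_j = j
        picked.append(best_j)
        candidates = [j for j in candidates if abs(j - best_j) >= w]
    return picked


# --- interval metrics -------------------------------------------------------


def brute_intersection(x: tuple[float, float], y: tuple[float, float]) -> float:
    lo = max(x[0], y[0])
    hi = min(x[1], y[1])
    return hi - lo if hi > lo else 0.0


def brute_dice(x: tuple[float, float], y: tuple[float, float]) -> float:
    return 2.0 * brute_intersection(x, y) / ((x[1] - x[0]) + (y[1] - y[0]))


def brute_match(x, intervals) -> int:
    """0-based index of the max-intersection interval, ties to minimum."""
    best, best_j = -1.0, 0
    for j, y in enumerate(intervals):
        i = brute_intersection(x, y)
        if i > best:
            best, best_j = i, j
    return best_j


def brute_mds(x, expert_interval_lists) -> float:
    """MDS of x over a list of per-expert interval lists."""
    out = 0.0
    for intervals in expert_interval_lists:
        c = brute_match(x, intervals)
        out = max(out, brute_dice(x, intervals[c]))
    return out


def brute_precision(mds_values, tau: float) -> float:
    return sum(1 for v in mds_values if v > tau) / len(mds_values)
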