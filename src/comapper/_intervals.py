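"""Interval primitives on 0-based half-open coordinates.

Thin numpy searchsorted machinery shared by the masking and enrichment layers.
All functions operate on one chromosome at a time; callers group by chromosome.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent intervals into a sorted disjoint set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def count_overlaps(q_start, q_end, t_start, t_end) -> np.ndarray:
    """Number of target intervals overlapping (>=1 bp) each query interval.

    Targets need not be disjoint.  Uses the identity
    #overlaps = #(t_start < q_end) - #(t_end <= q_start).
    """
    q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
    q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
    ts = np.sort(np.asarray(t_start, dtype=np.int64))
    te = np.sort(np.asarray(t_end, dtype=np.int64))
    if ts.size == 0:
        return np.zeros(q_start.shape, dtype=np.int64)
    lo = np.searchsorted(ts, q_end, side="left")
    hi = np.searchsorted(te, q_start, side="right")
    return lo - hi


def overlaps_any(q_start, q_end, t_start, t_end) -> np.ndarray:
    """Boolean mask: does each query overlap at least one target interval."""
    return count_overlaps(q_start, q_end, t_start, t_end) > 0


def points_in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask over 0-based points falling inside any interval (may overlap)."""
    points = np.asarray(points, dtype=np.int64)
    return overlaps_any(points, points + 1, starts, ends)


def gap_distance(q_start, q_end, t_start, t_end):
    """Distance in bp from each query to its nearest target interval (0 if touching)."""
    q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
    q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
    ms, me = merge_intervals(np.asarray(t_start), np.asarray(t_end))
    if ms.size == 0:
        return np.full(q_start.shape, np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.searchsorted(ms, q_end, side="left")
    right_gap = np.where(idx < ms.size, ms[np.minimum(idx, ms.size - 1)] - q_end, np.iinfo(np.int64).max)
    idx2 = np.searchsorted(me, q_start, side="right") - 1
    left_gap = np.where(idx2 >= 0, q_start - me[np.maximum(idx2, 0)], np.iinfo(np.int64).max)
    dist = np.minimum(np.maximum(right_gap, 0), np.maximum(left_gap, 0))
    covered = overlaps_any(q_start, q_end, ms, me)
    return np.where(covered, 0, dist)
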