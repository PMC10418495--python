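"""Denaturation-bubble statistics from broken-bond masks.

A *bubble* is a maximal run of consecutive broken base pairs.  Runs are
binned by length: an open state (OS) is a lone broken pair (1 bp); group 1
holds small bubbles (2–4 bp), group 2 metastable bubbles (5–10 bp), group 3
large bubbles (11–30 bp), group 4 very large bubbles (>30 bp).

For a mask at sample time t_j, the occupancy fraction q_j of a size group
is the number of broken pairs lying in bubbles of that group divided by the
total pair count n.  The occurrence probability P of the group is the
arithmetic mean of q_j over the recorded samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import BondTrajectory

__all__ = [
    "SIZE_GROUPS",
    "GROUP_ORDER",
    "BubbleRun",
    "decompose_runs",
    "occupancy_fraction",
    "occupancy_fractions",
    "occupancy_probability",
    "occupancy_probabilities",
]

#: group name -> (min length, max length) in base pairs, inclusive.
SIZE_GROUPS: dict[str, tuple[int, int]] = {
    "OS": (1, 1),
    "group1": (2, 4),
    "group2": (5, 10),
    "group3": (11, 30),
    "group4": (31, np.iinfo(np.int64).max),
}
GROUP_ORDER = tuple(SIZE_GROUPS)


@dataclass(frozen=True)
class BubbleRun:
    """Maximal run of broken pairs: 1-based start and length in bp."""

    start: int
    length: int


def decompose_runs(mask: np.ndarray) -> list[BubbleRun]:
    """Maximal runs of True values in a broken-pair mask, left to right."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 1:
        raise ValueError("mask must be one-dimensional")
    padded = np.concatenate(([False], m, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [BubbleRun(int(s) + 1, int(e - s)) for s, e in zip(starts, ends)]


def occupancy_fraction(mask: np.ndarray, group: str) -> float:
    """Fraction of the sequence covered by bubbles in one size group."""
    return occupancy_fractions(mask)[group]


def occupancy_fractions(mask: np.ndarray) -> dict[str, float]:
    """q for every size group of one mask (sums to broken-count / n)."""
    m = np.asarray(mask, dtype=bool)
    n = m.shape[0]
    totals = dict.fromkeys(GROUP_ORDER, 0)
    for run in decompose_runs(m):
        for g, (lo, hi) in SIZE_GROUPS.items():
            if lo <= run.length <= hi:
                totals[g] += run.length
                break
    return {g: totals[g] / n for g in GROUP_ORDER}


def tail_occupancy_fraction(mask: np.ndarray, min_length: int) -> float:
    """Fraction of pairs lying in bubbles of length >= *min_length*.

    Unlike per-group occupancy, this cumulative form is weakly
    non-increasing when the mask shrinks (e.g. re-thresholding the same
    trajectory at a higher critical energy): every run of the smaller mask
    sits inside a run of the larger one.
    """
    m = np.asarray(mask, dtype=bool)
    total = sum(r.length for r in decompose_runs(m) if r.length >= min_length)
    return total / m.shape[0]


def occupancy_probability(traj: BondTrajectory, group: str) -> float:
    """Mean over samples of the group's occupancy fraction."""
    return occupancy_probabilities(traj)[group]


def occupancy_probabilities(traj: BondTrajectory) -> dict[str, float]:
    """P for every size group: the per-sample q averaged over the trajectory."""
    if traj.samples < 1:
        raise ValueError("trajectory has no recorded samples")
    acc = dict.fromkeys(GROUP_ORDER, 0.0)
    for j in range(traj.samples):
        q = occupancy_fractions(traj.broken[j])
        for g in GROUP_ORDER:
            acc[g] += q[g]
    return {g: acc[g] / traj.samples for g in GROUP_ORDER}
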