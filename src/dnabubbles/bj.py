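"""Extremum-range classification of substitution positions (modified BJ).

For each (critical energy, bubble size group) the per-position occurrence
probabilities P_i are compared with the all-protium baseline P0 and the
extremes Pimax, Pimin.  Positions close enough to Pimax form the "Maximum"
range (count nmax); positions close enough to Pimin form the "Minimum"
range (count nmin).  The inner cut is one tenth of the Pimax-Pimin span
when that still clears the midpoint toward P0, otherwise one quarter of the
distance to P0:

Maximum (requires Pimax > P0 >= Pimin >= 0):
    if Pimax - (Pimax - Pimin)/10 >= P0 + (Pimax - P0)/2:
        members are {i : P_i >= Pimax - (Pimax - Pimin)/10}
    else:
        members are {i : P_i >= Pimax - (Pimax - P0)/4}

Minimum (requires Pimax != Pimin > 0):
    if Pimin + (Pimax - Pimin)/10 <= P0 - (P0 - Pimin)/2:
        members are {i : P_i <= Pimin + (Pimax - Pimin)/10}
    else:
        members are {i : P_i <= Pimin + (P0 - Pimin)/4}

When Pimin = 0 the minimum range degenerates into the closed states
(positions with P_i = 0, count n_CS over the whole gene of n_g pairs) and a
differentiated count replaces the raw tally to damp false positives:

    effective_nmin = n_CS * (1 - (n_CS / n_g)**2)

which approaches n_CS for rare closed states and 0 when every position is
closed.  An alternative reading n_CS * (1 - n_CS / n_g)**2 of the same
correction is available behind ``alt_closed_parse``.  All threshold
comparisons are non-strict, so ties at a threshold are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .bubbles import GROUP_ORDER
from .duplex import GeneDuplex, RegionPartition
from .scan import BubbleProfile

__all__ = [
    "BJRangeResult",
    "bj_max_range",
    "bj_min_range",
    "classify_profile",
    "closed_state_census",
    "summarize_ranges",
    "aggregate_at_percent",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (presentation rounding for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BJRangeResult:
    """Membership of one (energy, group) cell."""

    energy: str
    group: str
    max_members: frozenset[int]
    min_members: frozenset[int]
    closed_positions: frozenset[int]
    max_threshold: float | None
    min_threshold: float | None
    effective_nmin: float
    all_closed: bool  # every position has P_i = 0 (the "-" table cells)

    @property
    def nmax(self) -> int:
        return len(self.max_members)

    @property
    def nmin(self) -> int:
        return len(self.min_members)


def bj_max_range(
    pi: np.ndarray, p0: float
) -> tuple[frozenset[int], float | None]:
    """"Maximum"-range membership (1-based positions) and the threshold used."""
    pi = np.asarray(pi, dtype=float)
    pmax = float(pi.max())
    pmin = float(pi.min())
    if not (pmax > p0 >= pmin >= 0):
        return frozenset(), None
    t10 = pmax - (pmax - pmin) / 10.0
    if t10 >= p0 + (pmax - p0) / 2.0:
        thr = t10
    else:
        thr = pmax - (pmax - p0) / 4.0
    members = frozenset(int(i) + 1 for i in np.flatnonzero(pi >= thr))
    return members, thr


def bj_min_range(
    pi: np.ndarray,
    p0: float,
    n_g: int,
    alt_closed_parse: bool = False,
) -> tuple[frozenset[int], float | None, float]:
    """"Minimum"-range membership, threshold, and the effective count.

    Returns ``(members, threshold, effective_nmin)``.  In the ordinary case
    (Pimin > 0, Pimax != Pimin) effective_nmin equals the raw member count;
    in the closed-state case (Pimin = 0) the members are the closed
    positions and effective_nmin carries the differentiated count.
    """
    pi = np.asarray(pi, dtype=float)
    pmax = float(pi.max())
    pmin = float(pi.min())
    if pmin > 0 and pmax != pmin:
        t10 = pmin + (pmax - pmin) / 10.0
        if t10 <= p0 - (p0 - pmin) / 2.0:
            thr = t10
        else:
            thr = pmin + (p0 - pmin) / 4.0
        members = frozenset(int(i) + 1 for i in np.flatnonzero(pi <= thr))
        return members, thr, float(len(members))
    if pmin == 0:
        closed = frozenset(int(i) + 1 for i in np.flatnonzero(pi == 0.0))
        n_cs = len(closed)
        ratio = n_cs / n_g
        if not 0 < ratio <= 1:
            return frozenset(), None, 0.0
        if alt_closed_parse:
            eff = n_cs * (1.0 - ratio) ** 2
        else:
            eff = n_cs * (1.0 - ratio**2)
        return closed, None, eff
    # Pimax == Pimin > 0: a flat profile defines no minimum range.
    return frozenset(), None, 0.0


def closed_state_census(
    profile: BubbleProfile,
    energy: str,
    group: str,
    partition: RegionPartition,
) -> dict[str, int]:
    """Per-region counts of positions with P_i = 0 at one (energy, group)."""
    pi = profile.pi_vector(energy, group)
    census = dict.fromkeys(partition.names, 0)
    for idx in np.flatnonzero(pi == 0.0):
        census[partition.region_of(int(idx) + 1)] += 1
    return census


def classify_profile(
    profile: BubbleProfile,
    alt_closed_parse: bool = False,
) -> dict[tuple[str, str], BJRangeResult]:
    """Run the BJ classification for every (energy, group) in a profile."""
    results: dict[tuple[str, str], BJRangeResult] = {}
    for energy in profile.energies:
        for group in GROUP_ORDER:
            pi = profile.pi_vector(energy, group)
            p0 = profile.p0(energy, group)
            max_members, max_thr = bj_max_range(pi, p0)
            min_members, min_thr, eff = bj_min_range(
                pi, p0, profile.n, alt_closed_parse=alt_closed_parse
            )
            closed = frozenset(int(i) + 1 for i in np.flatnonzero(pi == 0.0))
            results[(energy, group)] = BJRangeResult(
                energy=energy,
                group=group,
                max_members=max_members,
                min_members=min_members,
                closed_positions=closed,
                max_threshold=max_thr,
                min_threshold=min_thr,
                effective_nmin=eff,
                all_closed=len(closed) == profile.n,
            )
    return results


def summarize_ranges(
    results: dict[tuple[str, str], BJRangeResult],
    duplex: GeneDuplex,
    partition: RegionPartition,
) -> pd.DataFrame:
    """Region-wise counts and A–T tallies for both ranges.

    Long-format DataFrame with columns energy, region, group, range
    ("Maximum"/"Minimum"), n, at, all_closed, effective_nmin (gene-level,
    repeated on Minimum rows; NaN on Maximum rows).  Raw member counts fill
    ``n``; the differentiated closed-state count stays in its own column.
    """
    weak = duplex.is_weak()
    rows = []
    for (energy, group), res in sorted(results.items()):
        for range_name, members in (
            ("Maximum", res.max_members),
            ("Minimum", res.min_members),
        ):
            by_region = {name: [0, 0] for name in partition.names}
            for pos in members:
                reg = partition.region_of(pos)
                by_region[reg][0] += 1
                by_region[reg][1] += int(weak[pos - 1])
            for reg in partition.names:
                n, at = by_region[reg]
                rows.append(
                    {
                        "energy": energy,
                        "region": reg,
                        "group": group,
                        "range": range_name,
                        "n": n,
                        "at": at,
                        "all_closed": res.all_closed,
                        "effective_nmin": res.effective_nmin
                        if range_name == "Minimum"
                        else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def aggregate_at_percent(
    cells: pd.DataFrame,
    regions=None,
    groups=None,
    energies=None,
) -> tuple[int, int, float]:
    """Aggregate table cells and return (n total, A–T total, A–T percentage).

    *cells* is any long-format table with columns region, group, energy, n,
    at (all-closed cells contribute zero).  The percentage is rounded half
    away from zero to one decimal, matching tabular presentation.
    """
    sel = cells
    if regions is not None:
        sel = sel[sel["region"].isin(list(regions))]
    if groups is not None:
        sel = sel[sel["group"].isin(list(groups))]
    if energies is not None:
        sel = sel[sel["energy"].isin(list(energies))]
    n = int(sel["n"].sum())
    at = int(sel["at"].sum())
    pct = round_half_away(100.0 * at / n, 1) if n else float("nan")
    return n, at, pct
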