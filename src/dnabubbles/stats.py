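"""Association statistics for range-count and composition comparisons.

The 2x2 Yates chi-squared uses the classic shortcut

    chi2 = N * (|ad - bc| - N/2)^2 / (N_A * N_B * N_S * N_F)

with the conventional clamp: when |ad - bc| <= N/2 the continuity
correction would overshoot zero, so the statistic is 0.  The unclamped
value is exposed for audit.  The 3x2 test is the Pearson statistic with 2
degrees of freedom; its three pairwise 2x2 follow-ups carry
Bonferroni-multiplied p-values.  Kruskal-Wallis and Spearman delegate to
scipy with the documented edge cases handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "yates_chi2",
    "chi2_3x2_bonferroni",
    "kruskal_wallis",
    "spearman",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def N_A(self) -> int:
        return self.a + self.b

    @property
    def N_B(self) -> int:
        return self.c + self.d

    @property
    def N_S(self) -> int:
        return self.a + self.c

    @property
    def N_F(self) -> int:
        return self.b + self.d

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def yates_chi2(table: ContingencyTable2x2) -> tuple[float, float, int]:
    """Yates-corrected chi-squared for a 2x2 table: (statistic, p, dof=1).

    Raises on a zero margin (the statistic is undefined there).
    """
    margins = (table.N_A, table.N_B, table.N_S, table.N_F)
    if any(m == 0 for m in margins):
        raise ValueError("all four margins must be positive")
    stat = _yates_statistic(table, clamp=True)
    p = float(sps.chi2.sf(stat, 1))
    return stat, p, 1


def _yates_statistic(table: ContingencyTable2x2, clamp: bool) -> float:
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    N = table.N
    diff = abs(a * d - b * c) - N / 2.0
    if clamp:
        diff = max(diff, 0.0)
    num = N * diff**2
    den = float(table.N_A) * table.N_B * table.N_S * table.N_F
    return num / den


def yates_chi2_unclamped(table: ContingencyTable2x2) -> float:
    """The literal shortcut value without flooring the corrected difference."""
    if any(m == 0 for m in (table.N_A, table.N_B, table.N_S, table.N_F)):
        raise ValueError("all four margins must be positive")
    return _yates_statistic(table, clamp=False)


def chi2_3x2_bonferroni(table) -> tuple[float, float, int, list[tuple[str, float]]]:
    """Omnibus Pearson chi-squared on a 3x2 table plus pairwise follow-ups.

    Returns (statistic, p, dof=2, pairwise) where pairwise holds the three
    row-pair comparisons as (label, Bonferroni-adjusted p) with the Yates
    2x2 test, factor 3, capped at 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 2):
        raise ValueError(f"expected a 3x2 table, got shape {t.shape}")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("all row and column margins must be positive")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    pairs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        sub = ContingencyTable2x2(*(int(x) for x in (*t[i], *t[j])))
        _, pp, _ = yates_chi2(sub)
        pairs.append((f"row{i + 1}-vs-row{j + 1}", min(1.0, 3.0 * pp)))
    return float(stat), float(p), int(dof), pairs


def kruskal_wallis(*samples) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction: (H, p).

    Degenerate all-identical data returns (0.0, 1.0) rather than erroring.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    flat = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties: (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for zero-variance input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
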