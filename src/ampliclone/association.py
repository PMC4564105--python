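"""Exact 2x2 association testing between cohort positivity prevalences.

The two-sided Fisher p-value uses the probability-mass convention: the
sum of hypergeometric probabilities, over all tables sharing the observed
margins, that do not exceed the observed table's probability (with a
small relative tolerance guarding floating-point ties).  Probabilities
are computed through log-gamma, so large margins do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .calling import CohortCallSummary
from .errors import GroupingError
from .tables import Cohort

__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "fisher_exact_two_sided",
    "fisher_exact_one_sided",
    "odds_ratio",
    "build_association",
]

TIE_RELATIVE_TOLERANCE = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """Counts laid out as rows = group, columns = (positive, negative)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 entries must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    table: TwoByTwo
    p_two_sided: float
    odds_ratio: float
    prevalence_per_group: tuple[float, float]


def _log_hypergeom_pmf(x: np.ndarray, n_total: int, row1: int, col1: int) -> np.ndarray:
    # log P(X = x) for X ~ Hypergeom(N, row1, col1)
    def lchoose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return lchoose(row1, x) + lchoose(n_total - row1, col1 - x) - lchoose(n_total, col1)


def _support(table: TwoByTwo) -> tuple[np.ndarray, np.ndarray, int]:
    a, b, c, d = table.cells
    row1, row2 = a + b, c + d
    col1 = a + c
    n_total = row1 + row2
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(xs, n_total, row1, col1)
    return xs, logp, a


def fisher_exact_two_sided(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p by full enumeration over the support.

    Degenerate tables (an empty margin) return 1.0.
    """
    a, b, c, d = table.cells
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    xs, logp, a_obs = _support(table)
    p = np.exp(logp)
    p_obs = p[xs == a_obs][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + TIE_RELATIVE_TOLERANCE)].sum()))


def fisher_exact_one_sided(table: TwoByTwo) -> float:
    """Smaller of the two exact tail probabilities (includes the observed table)."""
    a, b, c, d = table.cells
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    xs, logp, a_obs = _support(table)
    p = np.exp(logp)
    return float(min(1.0, min(p[xs <= a_obs].sum(), p[xs >= a_obs].sum())))


def odds_ratio(table: TwoByTwo, continuity: float = 0.0) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    With ``continuity=0`` a Haldane correction of 0.5 is applied
    automatically when any cell is zero; an explicit constant is added to
    every cell.
    """
    a, b, c, d = (float(v) for v in table.cells)
    if continuity == 0.0 and min(a, b, c, d) == 0.0:
        continuity = 0.5
    a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
    if b * c == 0.0:
        return float("inf")
    return (a * d) / (b * c)


def build_association(
    summary: CohortCallSummary,
    groups: tuple[str, str] | None = None,
) -> AssociationResult:
    """Assemble the 2x2 from a call summary and test it.

    ``groups`` selects and orders the two compared cohorts; by default the
    two non-reference groups present are used in cohort-declaration order
    (WM-family first).  Raises :class:`GroupingError` unless exactly two
    groups are available.
    """
    if groups is None:
        order = [c.value for c in Cohort if c is not Cohort.REFERENCE]
        groups_found = [g for g in order if g in summary.groups]
        # also accept any non-reference custom labels, preserving summary order
        for g in summary.groups:
            if g not in groups_found and g != Cohort.REFERENCE.value:
                groups_found.append(g)
        if len(groups_found) != 2:
            raise GroupingError(
                f"need exactly two non-reference groups, found {groups_found}"
            )
        groups = (groups_found[0], groups_found[1])
    for g in groups:
        if g not in summary.groups:
            raise GroupingError(f"group {g!r} absent from summary")

    g1, g2 = (summary.groups[g] for g in groups)
    table = TwoByTwo(
        a=g1.positive,
        b=g1.evaluable - g1.positive,
        c=g2.positive,
        d=g2.evaluable - g2.positive,
    )
    prev = tuple(
        (g.positive / g.evaluable) if g.evaluable else 0.0 for g in (g1, g2)
    )
    return AssociationResult(
        table=table,
        p_two_sided=fisher_exact_two_sided(table),
        odds_ratio=odds_ratio(table),
        prevalence_per_group=prev,  # type: ignore[arg-type]
    )
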