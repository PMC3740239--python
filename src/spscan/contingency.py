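"""Stratified 2x2 contingency analysis.

The classic discrete face of Simpson's paradox: an association between a
binary group variable and a binary outcome can point one way in every
stratum and the opposite way once the strata are amalgamated (summed
cell-wise). This module provides the amalgamation arithmetic, Pearson
chi-square independence tests (Yates-corrected by default for 2x2
tables), exact association signs via integer cross-products, and a scan
that classifies a stratified table as showing no, partial, or full sign
reversal.

Association sign convention: ``sign(p1 - p2)`` where ``p1 = n11/(n11+n12)``
is the group-1 success proportion and ``p2 = n21/(n21+n22)`` the group-2
one. On count (or probability) tables this is evaluated exactly through
the determinant ``n11*n22 - n12*n21``, avoiding floating-point ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .errors import DataError, DegenerateMarginError

__all__ = [
    "StratumTable",
    "StratifiedTable",
    "AssociationResult",
    "TableSPReport",
    "PooledRate",
    "amalgamate",
    "chi2_independence",
    "conditional_independence_scan",
    "pooled_rate",
]


@dataclass(frozen=True)
class StratumTable:
    """One labeled 2x2 table: two groups (rows) by success/failure (columns).

    Cells may be counts or, for the random-table prevalence study,
    probabilities; all must be finite and non-negative.
    """

    label: str
    n11: float  # group-1 successes
    n12: float  # group-1 failures
    n21: float  # group-2 successes
    n22: float  # group-2 failures

    def __post_init__(self) -> None:
        cells = (self.n11, self.n12, self.n21, self.n22)
        if not all(np.isfinite(c) for c in cells):
            raise DataError(f"stratum {self.label!r}: non-finite cell")
        if any(c < 0 for c in cells):
            raise DataError(f"stratum {self.label!r}: negative cell")

    @property
    def total(self) -> float:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def cells(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]], dtype=float)

    @property
    def p1(self) -> float:
        """Group-1 success proportion."""
        return self.n11 / (self.n11 + self.n12)

    @property
    def p2(self) -> float:
        """Group-2 success proportion."""
        return self.n21 / (self.n21 + self.n22)

    def association_sign(self) -> int:
        """Sign of p1 - p2, computed exactly via the table determinant.

        ``p1 - p2`` has the sign of ``n11*n22 - n12*n21`` whenever both row
        totals are positive, so integer tables never produce float ties.
        """
        det = self.n11 * self.n22 - self.n12 * self.n21
        return int(np.sign(det))

    def has_zero_margin(self) -> bool:
        return (
            self.n11 + self.n12 == 0
            or self.n21 + self.n22 == 0
            or self.n11 + self.n21 == 0
            or self.n12 + self.n22 == 0
        )


@dataclass(frozen=True)
class StratifiedTable:
    """Ordered collection of uniquely-labeled strata."""

    strata: tuple[StratumTable, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise DataError(f"duplicate stratum labels: {labels}")

    def __len__(self) -> int:
        return len(self.strata)


@dataclass(frozen=True)
class AssociationResult:
    """Chi-square independence test outcome plus the association sign."""

    statistic: float
    df: int
    p_value: float
    sign: int
    corrected: bool


@dataclass(frozen=True)
class TableSPReport:
    """Outcome of a conditional-independence scan over a stratified table.

    ``reversal`` is "full" when every testable stratum's sign opposes a
    nonzero aggregate sign, "partial" when some but not all do, "none"
    otherwise. Classification uses signs only; ``significant_reversal``
    additionally requires every involved test to reach ``alpha``.
    """

    aggregate: AssociationResult
    per_stratum: dict[str, AssociationResult]
    untestable: tuple[str, ...]
    reversal: str  # none | partial | full
    significant_reversal: bool
    alpha: float
    narrative: str


@dataclass(frozen=True)
class PooledRate:
    """Aggregate success rate with the per-stratum rates that compose it."""

    pooled: float
    per_stratum: tuple[float, ...]
    successes: float
    trials: float


def amalgamate(strat: StratifiedTable) -> StratumTable:
    """Sum a stratified table cell-wise into a single pooled 2x2 table.

    Amalgamation conserves every cell total exactly; it is the aggregation
    step under which Simpson reversals arise.
    """
    if len(strat) == 0:
        raise DataError("cannot amalgamate an empty stratified table")
    cells = np.sum([s.cells for s in strat.strata], axis=0)
    return StratumTable("Combined", cells[0, 0], cells[0, 1], cells[1, 0], cells[1, 1])


def chi2_independence(
    table: StratumTable, use_continuity_correction: bool = True
) -> AssociationResult:
    """Pearson chi-square test of independence on a 2x2 table.

    With ``use_continuity_correction`` (the default) the Yates correction
    is applied: 0.5 is subtracted from each ``|observed - expected|``
    (floored at zero) before squaring. df is always 1.

    Raises
    ------
    DegenerateMarginError
        If any row or column total is zero, in which case expected
        frequencies are undefined.
    """
    if table.total <= 0:
        raise DegenerateMarginError(f"stratum {table.label!r}: empty table")
    if table.has_zero_margin():
        raise DegenerateMarginError(
            f"stratum {table.label!r}: zero row or column margin, test undefined"
        )
    res = chi2_contingency(table.cells, correction=use_continuity_correction)
    return AssociationResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        sign=table.association_sign(),
        corrected=use_continuity_correction,
    )


def conditional_independence_scan(
    strat: StratifiedTable,
    use_continuity_correction: bool = True,
    alpha: float = 0.05,
) -> TableSPReport:
    """Test the amalgamated table and every stratum; classify sign reversal.

    Strata with a zero margin are untestable: they are excluded from the
    reversal vote and listed in the report rather than failing the scan.
    """
    combined = amalgamate(strat)
    try:
        aggregate = chi2_independence(combined, use_continuity_correction)
    except DegenerateMarginError as exc:
        raise DegenerateMarginError(f"aggregate table degenerate: {exc}") from exc

    per_stratum: dict[str, AssociationResult] = {}
    untestable: list[str] = []
    for s in strat.strata:
        if s.has_zero_margin() or s.total <= 0:
            untestable.append(s.label)
            continue
        per_stratum[s.label] = chi2_independence(s, use_continuity_correction)

    agg_sign = aggregate.sign
    opposing = [
        lab for lab, r in per_stratum.items() if agg_sign != 0 and r.sign == -agg_sign
    ]
    if agg_sign != 0 and per_stratum and len(opposing) == len(per_stratum):
        reversal = "full"
    elif opposing:
        reversal = "partial"
    else:
        reversal = "none"

    significant_reversal = (
        reversal == "full"
        and aggregate.p_value <= alpha
        and all(per_stratum[lab].p_value <= alpha for lab in opposing)
    )

    if reversal == "none":
        narrative = "No stratum opposes the aggregate association sign."
    else:
        narrative = (
            f"{reversal.capitalize()} reversal: strata {', '.join(sorted(opposing))} "
            f"oppose the aggregate association sign ({'+' if agg_sign > 0 else '-'})."
        )
    if untestable:
        narrative += f" Untestable strata (zero margin): {', '.join(untestable)}."

    return TableSPReport(
        aggregate=aggregate,
        per_stratum=per_stratum,
        untestable=tuple(untestable),
        reversal=reversal,
        significant_reversal=significant_reversal,
        alpha=alpha,
        narrative=narrative,
    )


def pooled_rate(strata_rates: Sequence[tuple[float, float]]) -> PooledRate:
    """Pool per-stratum (successes, trials) into an aggregate success rate.

    The pooled rate is a trials-weighted average of the per-stratum rates,
    which is why a unit can lead in every stratum yet trail overall (the
    two-researchers acceptance-rate pattern). Per-stratum rates are
    returned alongside the pooled value so the reversal is visible.
    """
    if not strata_rates:
        raise DataError("no strata given")
    for k, n in strata_rates:
        if n <= 0:
            raise DataError("every stratum needs trials > 0")
        if k < 0 or k > n:
            raise DataError(f"successes {k} outside [0, {n}]")
    successes = sum(k for k, _ in strata_rates)
    trials = sum(n for _, n in strata_rates)
    return PooledRate(
        pooled=successes / trials,
        per_stratum=tuple(k / n for k, n in strata_rates),
        successes=successes,
        trials=trials,
    )


#: Stylized two-faculty admission fixture (males x accepted), the canonical
#: full-reversal example: combined rates 0.84 vs 0.78 favor group 1, yet
#: both strata favor group 2.
BERKELEY = StratifiedTable(
    (
        StratumTable("Faculty A", 820, 80, 680, 20),
        StratumTable("Faculty B", 20, 80, 100, 200),
    )
)
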