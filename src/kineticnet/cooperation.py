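"""Factor-cooperation analysis via stratified 2x2 tables and odds ratios.

Genes are cross-classified by dynamic status and by proximity to a second
factor's inferred regulatory elements, within strata defined by proximity to
a first factor.  An increase in the dynamic-status odds ratio from the
A-absent stratum to the A-present stratum indicates that the two factors
cooperate.  Confidence intervals are Woolf (normal on the log odds ratio)
with the Haldane-Anscombe +0.5 correction when any cell is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np
from scipy import stats

__all__ = ["ContingencyTable", "OddsRatioCI", "stratified_tables", "odds_ratio_ci"]


@dataclass(frozen=True)
class ContingencyTable:
    """Gene counts: rows dynamic / not dynamic, columns proximal / not to B.

    a = dynamic & proximal, b = dynamic & not, c = not dynamic & proximal,
    d = neither; all within one stratum of factor-A proximity.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioCI:
    odds_ratio: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0 < self.lower <= self.odds_ratio <= self.upper):
            raise ValueError("CI must bracket the odds ratio with positive bounds")


def stratified_tables(genes: Iterable[str], dynamic: Collection[str],
                      proximal_a: Collection[str], proximal_b: Collection[str],
                      ) -> tuple[ContingencyTable, ContingencyTable]:
    """Two 2x2 tables of dynamic status vs factor-B proximity, stratified by A.

    Returns (A-absent stratum, A-present stratum).  The four cells partition
    each stratum exactly; an empty stratum yields a table of zeros.
    """
    genes = list(genes)
    dynamic, prox_a, prox_b = set(dynamic), set(proximal_a), set(proximal_b)
    tables = []
    for in_a in (False, True):
        stratum = [g for g in genes if (g in prox_a) == in_a]
        a = sum(1 for g in stratum if g in dynamic and g in prox_b)
        b = sum(1 for g in stratum if g in dynamic and g not in prox_b)
        c = sum(1 for g in stratum if g not in dynamic and g in prox_b)
        d = sum(1 for g in stratum if g not in dynamic and g not in prox_b)
        tables.append(ContingencyTable(a, b, c, d))
    return tables[0], tables[1]


def odds_ratio_ci(table: ContingencyTable, confidence: float = 0.95) -> OddsRatioCI:
    """Woolf CI: exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

    The Haldane-Anscombe correction adds 0.5 to every cell when any cell
    is zero (and for the standard error, which always uses the corrected
    cells when needed).
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if table.has_zero_cell:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return OddsRatioCI(float(or_), float(or_ * np.exp(-z * se)),
                       float(or_ * np.exp(z * se)))
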