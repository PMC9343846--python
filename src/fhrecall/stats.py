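"""Exact two-tailed Fisher tests and group comparison tables.

The group comparisons (recalled carriers vs never-recalled controls) use
Fisher's exact test with the minimum-likelihood two-tailed definition:
the p-value is the sum of hypergeometric point probabilities, over all
2x2 tables with the observed margins, that do not exceed the point
probability of the observed table.  This is the definition used by
Langsrud's online calculator (after Agresti); the alternative
"doubling" definition gives different p-values and is deliberately not
offered.

Point probabilities are evaluated in log space so that cohort-scale
margins (n of a few hundred) never overflow, and ties are compared with
a small relative tolerance because equal probabilities on opposite
tails differ in their last floating-point bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: Relative tolerance when comparing point probabilities to the observed
#: table's probability; absorbs floating-point noise on tied tails.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Group x phenotype counts: rows are groups, columns yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(not isinstance(x, int) or x < 0 for x in cells):
            raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def _log_point_prob(x: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = x) for hypergeometric X with margins (r1, r2; c1)."""

    def lchoose(n: int, k: int) -> float:
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    return lchoose(r1, x) + lchoose(r2, c1 - x) - lchoose(r1 + r2, c1)


def hypergeom_point_prob(table) -> float:
    """Probability of the observed table conditional on its margins.

    P(X = a | margins) = C(a+b, a) * C(c+d, c) / C(n, a+c).
    """
    t = _as_table(table)
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    if t.a < max(0, c1 - r2) or t.a > min(r1, c1):
        raise ValueError(f"impossible margins for table {t}")
    return math.exp(_log_point_prob(t.a, r1, r2, c1))


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p-value by hypergeometric enumeration.

    Sums point probabilities of every same-margin table whose probability
    is <= that of the observed table (within ``TIE_RTOL`` relative
    tolerance).  The result lies in (0, 1]: the observed table always
    contributes its own probability.
    """
    t = _as_table(table)
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = _log_point_prob(t.a, r1, r2, c1)
    threshold = log_obs + math.log1p(TIE_RTOL)
    p = 0.0
    for x in range(lo, hi + 1):
        lp = _log_point_prob(x, r1, r2, c1)
        if lp <= threshold:
            p += math.exp(lp)
    return min(p, 1.0)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching conventional table layout."""
    factor = 10**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def percentage(count: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage at fixed precision with half-up rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, ndigits)


def compare_groups(
    flags: pd.DataFrame,
    phenotypes: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("RECALLED", "CONTROL"),
) -> pd.DataFrame:
    """Per-phenotype counts, percentages and exact p per group.

    Parameters
    ----------
    flags:
        One row per participant with a group column and one boolean
        column per phenotype.
    phenotypes:
        Names of the boolean columns to compare.

    Returns a table with explicit denominators: columns ``phenotype``,
    ``group1_n``, ``group1_total``, ``group1_pct``, ``group2_n``,
    ``group2_total``, ``group2_pct``, ``p_value``.
    """
    g1, g2 = groups
    f1 = flags[flags[group_col] == g1]
    f2 = flags[flags[group_col] == g2]
    if len(f1) == 0 or len(f2) == 0:
        raise ValueError(f"both groups must be nonempty; sizes {len(f1)}, {len(f2)}")
    rows = []
    for ph in phenotypes:
        a = int(f1[ph].sum())
        c = int(f2[ph].sum())
        b, d = len(f1) - a, len(f2) - c
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "phenotype": ph,
                "group1_n": a,
                "group1_total": len(f1),
                "group1_pct": percentage(a, len(f1)),
                "group2_n": c,
                "group2_total": len(f2),
                "group2_pct": percentage(c, len(f2)),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
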