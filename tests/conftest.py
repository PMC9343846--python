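import datetime as dt
from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from fhrecall.config import SimulationConfig


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-tailed Fisher p by brute enumeration.

    Independent of the package's log-space path: uses integer binomial
    coefficients and exact fraction comparison over every table with
    the observed margins.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    def point(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs)


def flags_from_counts(
    n1: int, k1: dict[str, int], n2: int, k2: dict[str, int]
) -> pd.DataFrame:
    """Boolean flag table with given per-group positive counts.

    Each phenotype's first k participants of a group are positive, so
    keyed-in published counts become a concrete cohort fixture.
    """
    rows = []
    for group, n, k in (("RECALLED", n1, k1), ("CONTROL", n2, k2)):
        for i in range(n):
            row = {"participant_id": f"{group[0]}{i:04d}", "group": group}
            for phenotype, count in k.items():
                row[phenotype] = i < count
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def table3_flags() -> pd.DataFrame:
    """Cohort fixture keyed to the published comparison-table counts."""
    return flags_from_counts(
        34,
        {"has_e78_any": 32, "has_e780": 28, "is_llt_user": 27, "risk_higher": 10},
        291,
        {"has_e78_any": 195, "has_e780": 134, "is_llt_user": 155, "risk_higher": 83},
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_recalled=8, n_controls=40, seed=11)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=3)


D = dt.date
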