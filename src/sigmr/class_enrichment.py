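"""Drug-class over-representation among high-connectivity references."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentTable2x2:
    """2x2 contingency table: class membership x high-connectivity status.

    a: class & high, b: class & not-high, c: non-class & high,
    d: non-class & not-high.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def threshold_classify(
    avg_tau: Mapping[str, float] | pd.Series,
    cutoff: float = 90.0,
    exclude: Iterable[str] = (),
) -> tuple[set[str], set[str]]:
    """Partition references into high (tau strictly > cutoff) and low sets.

    ``exclude`` removes the query compounds themselves from the universe
    before classification.
    """
    if not -100.0 <= cutoff <= 100.0:
        raise ValueError("cutoff must lie in [-100, 100]")
    s = pd.Series(avg_tau, dtype=float)
    s = s.drop(index=[e for e in exclude if e in s.index])
    high = set(s.index[s > cutoff])
    low = set(s.index) - high
    return high, low


def class_enrichment_test(
    table: EnrichmentTable2x2,
    correction: str = "none",
) -> tuple[float, float, float]:
    """Pearson chi-square test (1 df) of class x high-connectivity association.

    Returns (chi2, p, odds_ratio); odds ratio is ad/bc (inf when bc = 0).
    ``correction`` selects 'none' (default), 'yates', or 'fisher' (exact
    test; chi2 reported as NaN).
    """
    if any(m == 0 for m in table.margins):
        raise ValueError("all margins of the 2x2 table must be positive")
    arr = table.as_array()
    if correction == "fisher":
        odds, p = stats.fisher_exact(arr, alternative="two-sided")
        chi2 = float("nan")
    elif correction in ("none", "yates"):
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=(correction == "yates"))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    bc = table.b * table.c
    if bc == 0:
        odds_ratio = float("inf") if table.a * table.d > 0 else 0.0
    else:
        odds_ratio = (table.a * table.d) / bc
    return float(chi2), float(p), float(odds_ratio)


def build_enrichment_table(
    high: set[str],
    low: set[str],
    class_members: Iterable[str],
) -> EnrichmentTable2x2:
    """Assemble the 2x2 table for one drug class over a high/low partition."""
    cls = set(class_members) & (high | low)
    return EnrichmentTable2x2(
        a=len(cls & high),
        b=len(cls & low),
        c=len(high - cls),
        d=len(low - cls),
    )
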