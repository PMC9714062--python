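"""Exact Fisher test on 2×2 tables and the UBM-feature comparison.

Eyes whose achieved vault missed the prediction by more than 300 μm are
split into an overestimated (actual ≪ predicted) and an underestimated
(actual ≫ predicted) group; each boolean UBM feature is then compared
between the groups with the two-sided Fisher exact test.

The two-sided p-value follows the probability-mass convention (the sum of
hypergeometric point probabilities not exceeding the observed one), the
dominant convention for "Fisher exact probability" and the one SPSS and
scipy use; mid-p and doubling conventions give different values.  Point
probabilities come from ``scipy.stats.hypergeom``, which evaluates
log-factorials, so tables with totals in the hundreds stay exact to
double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import UBM_FEATURES

__all__ = [
    "ContingencyTable",
    "fisher_exact_two_sided",
    "compare_features",
]

#: Relative tolerance when comparing point probabilities to the observed
#: one — absorbs rounding noise in floating-point pmf values.
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: rows = error group (overestimated, underestimated),
    columns = feature (present, absent)."""

    a: int  # overestimated, feature present
    b: int  # overestimated, feature absent
    c: int  # underestimated, feature present
    d: int  # underestimated, feature absent

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name}={v!r} must be a nonnegative integer")
        if self.total == 0:
            raise ValueError("contingency table has zero total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def row_sums(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    def col_sums(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table.

    With margins fixed, the top-left count follows a hypergeometric
    distribution; p is the total probability of all tables whose point
    probability does not exceed the observed one (relative tolerance
    1+1e-7), clipped to [0, 1].
    """
    r1, _ = table.row_sums()
    c1, _ = table.col_sums()
    n = table.total

    k = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = hypergeom.pmf(k, n, c1, r1)
    p_obs = hypergeom.pmf(table.a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return min(max(p, 0.0), 1.0)


def compare_features(
    records: pd.DataFrame,
    features: tuple[str, ...] = UBM_FEATURES,
) -> pd.DataFrame:
    """Compare UBM-feature prevalence between the large-error groups.

    ``records`` needs an ``error_group`` column and one 0/1 (or boolean)
    column per feature.  Rows outside the overestimated/underestimated
    groups are ignored.  Returns one row per feature with counts,
    percentages (2 decimals) and the two-sided Fisher p-value.

    Raises ``ValueError`` if either group is empty.
    """
    if "error_group" not in records.columns:
        raise ValueError("records must carry an 'error_group' column")
    over = records[records["error_group"] == "overestimated"]
    under = records[records["error_group"] == "underestimated"]
    if over.empty or under.empty:
        raise ValueError(
            f"need both error groups nonempty, got {len(over)} overestimated "
            f"and {len(under)} underestimated"
        )

    rows = []
    for feat in features:
        if feat not in records.columns:
            raise ValueError(f"missing feature column {feat!r}")
        a = int(over[feat].astype(bool).sum())
        c = int(under[feat].astype(bool).sum())
        table = ContingencyTable(a, len(over) - a, c, len(under) - c)
        rows.append(
            {
                "feature": feat,
                "overestimated_n": len(over),
                "overestimated_count": a,
                "overestimated_pct": round(100.0 * a / len(over), 2),
                "underestimated_n": len(under),
                "underestimated_count": c,
                "underestimated_pct": round(100.0 * c / len(under), 2),
                "p_value": fisher_exact_two_sided(table),
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float, floor: float = 0.01) -> str:
    """Presentation-layer p-value formatting: 3 decimals, '<0.01' below floor."""
    return f"<{floor:g}" if p < floor else f"{p:.3f}"
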