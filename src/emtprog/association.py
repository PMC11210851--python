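"""Cross-tabulation of marker/model groups against clinicopathological factors.

Independence is tested with Pearson's chi-square (no continuity correction)
except on 2x2 tables where any expected count falls below 5, which switch to
Fisher's exact test (two-sided).  The method actually used is always carried
on the result, since the rule cannot be verified against the original
per-table choices.  p-values are two-sided and uncorrected for multiplicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "crosstab",
    "independence_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with labelled margins."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size == 0:
            raise ValueError("empty contingency table")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class AssociationResult:
    method: str  # "pearson_chi2" | "fisher_exact"
    statistic: float | None  #: chi-square statistic; None for Fisher
    df: int | None
    p: float
    dropped_rows: tuple = ()
    dropped_cols: tuple = ()


def crosstab(
    var_a: pd.Series,
    var_b: pd.Series,
    *,
    row_order=None,
    col_order=None,
) -> ContingencyTable:
    """Count label pairs over patients with both variables non-missing.

    ``row_order``/``col_order`` fix the declared category order (levels not
    observed are kept with zero counts so reports show the full layout).
    """
    paired = pd.DataFrame({"a": var_a, "b": var_b}).dropna()
    if paired.empty:
        raise ValueError("no patients with both variables observed")
    table = pd.crosstab(paired["a"], paired["b"])
    if row_order is not None:
        table = table.reindex(index=list(row_order), fill_value=0)
    if col_order is not None:
        table = table.reindex(columns=list(col_order), fill_value=0)
    table = table.fillna(0).astype(int)
    table.index.name = var_a.name or "a"
    table.columns.name = var_b.name or "b"
    return ContingencyTable(table)


def independence_test(table: ContingencyTable) -> AssociationResult:
    """Chi-square or Fisher test of row/column independence.

    Zero-margin rows/columns are dropped (with a warning) before testing;
    on the reduced table, a 2x2 with any expected count < 5 uses Fisher's
    exact test, anything else Pearson's chi-square without continuity
    correction.
    """
    counts = table.counts
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    dropped_rows = tuple(counts.index[~row_ok])
    dropped_cols = tuple(counts.columns[~col_ok])
    if dropped_rows or dropped_cols:
        warnings.warn(
            f"dropping zero-margin rows {list(dropped_rows)} / "
            f"columns {list(dropped_cols)} before independence test",
            stacklevel=2,
        )
        counts = counts.loc[row_ok, col_ok]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("independence test needs at least a 2x2 table")
    arr = counts.to_numpy()
    expected = stats.contingency.expected_freq(arr)
    if r == 2 and c == 2 and (expected < 5).any():
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return AssociationResult(
            method="fisher_exact", statistic=None, df=None, p=float(p),
            dropped_rows=dropped_rows, dropped_cols=dropped_cols,
        )
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return AssociationResult(
        method="pearson_chi2", statistic=float(chi2), df=int(df), p=float(p),
        dropped_rows=dropped_rows, dropped_cols=dropped_cols,
    )
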