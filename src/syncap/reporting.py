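"""Group comparisons and per-embryo aggregation.

The embryo is the unit of analysis: per-object measurements (caps,
furrows, spindles) are averaged within each embryo before genotypes are
compared with a Mann-Whitney U test. The exact U distribution is used
for small samples without ties; otherwise the tie-corrected normal
approximation, and the branch taken is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "mann_whitney", "aggregate_per_embryo"]

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}

#: largest combined sample size for which the exact U distribution is used
EXACT_MAX_N = 20


@dataclass
class ComparisonResult:
    group_names: tuple[str, str]
    n_per_group: tuple[int, int]
    u_statistic: float
    p_value: float
    medians: tuple[float, float]
    method: str
    alternative: str


def mann_whitney(
    x,
    y,
    alternative: str = "two_sided",
    group_names: tuple[str, str] = ("x", "y"),
) -> ComparisonResult:
    """Mann-Whitney U comparison of two independent samples.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties (within or across groups); otherwise
    the normal approximation with midranks and tie correction. The U
    statistic reported is for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (x.size + y.size) <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=_ALTERNATIVES[alternative],
        method="exact" if exact else "asymptotic",
    )
    return ComparisonResult(
        group_names=group_names,
        n_per_group=(int(x.size), int(y.size)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        medians=(float(np.median(x)), float(np.median(y))),
        method="exact" if exact else "asymptotic_tie_corrected",
        alternative=alternative,
    )


def aggregate_per_embryo(
    rows: pd.DataFrame, value_column: str, embryo_column: str = "embryo_id"
) -> pd.DataFrame:
    """One mean per embryo from per-object rows.

    Downstream tests compare these embryo-level means, never pooled
    per-object values, regardless of how many objects each embryo
    contributes.
    """
    if embryo_column not in rows.columns:
        raise ValueError(f"missing column {embryo_column!r}")
    if value_column not in rows.columns:
        raise ValueError(f"missing column {value_column!r}")
    if rows[embryo_column].isna().any():
        raise ValueError("rows with missing embryo id")
    out = (
        rows.groupby(embryo_column, sort=True)[value_column]
        .mean()
        .reset_index()
        .rename(columns={value_column: f"mean_{value_column}"})
    )
    return out
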