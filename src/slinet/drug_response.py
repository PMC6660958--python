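"""Biomarker-stratified drug sensitivity analysis.

Cell lines are split into low and high biomarker-expression groups at the
arithmetic mean of the marker (expression exactly at the mean goes low, a
deterministic convention). The IC50 distributions of the two groups are
compared with a two-sided Mann-Whitney U test; the more sensitive group is
the one with the smaller median IC50. IC50s are compared on the scale given
in the input (GDSC-style tables publish natural-log uM); since the test is
rank-based, any monotone transform of that scale gives the same P-value.

Dose-response summaries aggregate published per-concentration survival
percentages (mean +/- standard error per group); no curve fitting is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerSplit",
    "DrugSensitivityResult",
    "classify_by_marker",
    "test_sensitivity",
    "dose_response_summary",
]


class MarkerSplit(NamedTuple):
    """Low/high cell-line sets, the mean cutoff, and a degeneracy flag."""

    low: frozenset[str]
    high: frozenset[str]
    cutoff: float
    degenerate: bool


def classify_by_marker(marker_expr: Mapping[str, float] | pd.Series) -> MarkerSplit:
    """Split cell lines at the mean marker expression (<= mean goes low).

    When every value is identical, one side is empty; the split is returned
    with ``degenerate=True`` and downstream testing must refuse it.
    """
    expr = pd.Series(dict(marker_expr), dtype=float)
    if len(expr) < 2:
        raise ValueError("marker classification requires at least 2 cell lines")
    cutoff = float(expr.mean())
    low = frozenset(expr.index[expr <= cutoff])
    high = frozenset(expr.index[expr > cutoff])
    return MarkerSplit(low, high, cutoff, degenerate=(not low or not high))


@dataclass(frozen=True)
class DrugSensitivityResult:
    """Stratified Mann-Whitney outcome for one drug."""

    drug: str
    n_low: int
    n_high: int
    median_ic50_low: float
    median_ic50_high: float
    u_statistic: float
    p_value: float
    direction: str  # more-sensitive group: "low", "high" or "none"


def test_sensitivity(
    ic50_low: Sequence[float],
    ic50_high: Sequence[float],
    drug: str = "drug",
    alternative: str = "two-sided",
) -> DrugSensitivityResult:
    """Compare IC50 distributions between marker-low and marker-high lines.

    Mann-Whitney U with tie correction; the exact null is used when both
    groups have at most 8 values and no ties, otherwise the
    continuity-corrected normal approximation. The U statistic reported is
    for the low group. Fewer than 2 values in either group is a degenerate
    grouping and raises.
    """
    low = np.asarray(ic50_low, dtype=float)
    high = np.asarray(ic50_high, dtype=float)
    if low.size < 2 or high.size < 2:
        raise ValueError(
            "degenerate grouping: each marker group needs at least 2 IC50 values"
        )
    pooled = np.concatenate([low, high])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (low.size <= 8 and high.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        low, high, alternative=alternative, method=method, use_continuity=True
    )
    med_low, med_high = float(np.median(low)), float(np.median(high))
    if med_low < med_high:
        direction = "low"
    elif med_high < med_low:
        direction = "high"
    else:
        direction = "none"
    return DrugSensitivityResult(
        drug=drug,
        n_low=int(low.size),
        n_high=int(high.size),
        median_ic50_low=med_low,
        median_ic50_high=med_high,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
    )


def dose_response_summary(
    survival_by_group: Mapping[str, Iterable[Mapping[float, float]]]
) -> pd.DataFrame:
    """Per-dose mean and standard error of % survival, per group.

    ``survival_by_group`` maps group label -> iterable of per-cell-line
    concentration->survival mappings. Doses are unioned across lines within
    a group and sorted ascending. The SE is the sample standard deviation
    over the square root of n; a dose measured in a single line gets SE 0
    with ``se_defined = False``. An empty group raises.
    """
    rows = []
    for group, tables in survival_by_group.items():
        tables = list(tables)
        if not tables:
            raise ValueError(f"group {group!r} has no cell lines")
        doses = sorted({d for t in tables for d in t})
        for dose in doses:
            vals = np.array([t[dose] for t in tables if dose in t], dtype=float)
            if (vals < 0).any() or (vals > 100).any():
                raise ValueError("survival percentages must lie in [0, 100]")
            se_defined = vals.size > 1
            se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if se_defined else 0.0
            rows.append(
                {
                    "group": group,
                    "dose": dose,
                    "mean_survival": float(vals.mean()),
                    "se_survival": se,
                    "n": int(vals.size),
                    "se_defined": se_defined,
                }
            )
    return pd.DataFrame(rows).sort_values(["group", "dose"]).reset_index(drop=True)
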