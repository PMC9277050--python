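"""Biomarker dichotomization and clinical group comparisons.

A continuous methylation marker (e.g. an RQ-MSP level) is dichotomized at
the control-group "mean + 2 SD" cutoff: patients strictly above the cutoff
are hypermethylated, everyone at or below it is not. The two patient groups
are then compared variable by variable as clinical tables conventionally
are: continuous variables with the Mann-Whitney U (or Student t), 2x2
categorical tables with the Fisher exact test when any expected cell falls
below 5 and the Pearson chi-square otherwise, larger tables with the
chi-square.

The two-sided Fisher p-value follows the minimum-likelihood convention (the
sum of the probabilities of all tables with the observed margins whose
probability does not exceed the observed table's); this is the convention
that scipy implements and the one that reproduces published clinical-table
p-values such as the ones used in this package's tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "methylation_cutoff",
    "dichotomize",
    "fisher_exact_2x2",
    "pearson_chi2",
    "mann_whitney",
    "spearman",
    "compare_groups",
    "GroupComparison",
]

logger = logging.getLogger(__name__)


def methylation_cutoff(control_values: Sequence[float], ddof: int = 1) -> float:
    """Mean + 2 SD of the control values (sample SD, n-1, by default).

    Values strictly greater than the cutoff are labelled hypermethylated;
    values at or below it are not (the cutoff is the upper edge of the
    control envelope). ``ddof=0`` switches to the population SD.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two control values")
    return float(x.mean() + 2.0 * x.std(ddof=ddof))


def dichotomize(values: Sequence[float], cutoff: float) -> np.ndarray:
    """1 where value > cutoff (hypermethylated), else 0."""
    return (np.asarray(values, dtype=float) > cutoff).astype(int)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Minimum-likelihood two-sided convention. A degenerate margin (an all-zero
    row or column) gives p = 1 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table is empty")
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        logger.warning("degenerate margin in 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def pearson_chi2(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c table.

    Returns (statistic, p). Zero expected cells raise with a pointer to the
    Fisher branch.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin: use the Fisher exact test instead")
    stat, p, _, expected = stats.chi2_contingency(obs, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected cell: use the Fisher exact test instead")
    return float(stat), float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact permutation distribution when n1 + n2 <= 12 and there are no ties,
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one value per group")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (mid-ranks) and its t-approximation p-value.

    Returns (rho, p); a constant input vector yields (nan, nan) with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("constant vector in spearman; rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class GroupComparison:
    """Result of one clinical-table row comparison."""

    variable: str
    test: str
    p_value: float
    statistic: Optional[float] = None
    summary: Optional[str] = None


def _expected_cells(table: np.ndarray) -> np.ndarray:
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    return rowsum * colsum / table.sum()


def compare_groups(
    records: pd.DataFrame,
    variable: str,
    kind: str,
    group_col: str = "hypermethylated",
    continuous_test: str = "mannwhitney",
) -> GroupComparison:
    """Compare one variable between the two patient groups.

    Dispatch follows clinical-table convention: continuous variables go to
    the Mann-Whitney U (or ``continuous_test="ttest"``); categorical
    variables are cross-tabulated against the group, 2x2 tables with any
    expected cell < 5 go to the Fisher exact test, all other tables to the
    Pearson chi-square. Missing values (NaN) are dropped row-wise, so
    denominators may differ between variables.
    """
    if variable not in records.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if kind not in ("continuous", "categorical"):
        raise ValueError("kind must be 'continuous' or 'categorical'")
    sub = records[[group_col, variable]].dropna()
    if sub.empty:
        raise ValueError(f"variable {variable!r} has no non-missing values")

    if kind == "continuous":
        g1 = sub.loc[sub[group_col] == 1, variable].to_numpy(dtype=float)
        g0 = sub.loc[sub[group_col] == 0, variable].to_numpy(dtype=float)
        if g1.size == 0 or g0.size == 0:
            raise ValueError("a group has no observations")
        if continuous_test == "mannwhitney":
            p = mann_whitney(g1, g0)
            test = "mann-whitney"
        elif continuous_test == "ttest":
            from .diffmeth import compare_global

            p = compare_global(g1, g0) if g1.size > 1 and g0.size > 1 else np.nan
            test = "t-test"
        else:
            raise ValueError(f"unknown continuous test {continuous_test!r}")
        summary = f"median {np.median(g1):.3g} vs {np.median(g0):.3g}"
        return GroupComparison(variable, test, p, summary=summary)

    ct = pd.crosstab(sub[group_col], sub[variable])
    table = ct.to_numpy(dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"variable {variable!r} is constant within the data")
    if table.shape == (2, 2) and (_expected_cells(table) < 5).any():
        a, b = int(table[0, 0]), int(table[0, 1])
        c, d = int(table[1, 0]), int(table[1, 1])
        p = fisher_exact_2x2(a, b, c, d)
        return GroupComparison(variable, "fisher", p, summary=f"{a}/{b} vs {c}/{d}")
    stat, p = pearson_chi2(table)
    return GroupComparison(variable, "chi-square", p, statistic=stat)
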