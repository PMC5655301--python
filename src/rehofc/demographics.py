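"""Cohort-table group comparisons.

Continuous variables (age, psychological scores) are compared by one-way
ANOVA between the two groups — with two groups F = t^2 of the pooled
two-sample t.  Categorical variables (sex, education level) use the Pearson
chi-square test without continuity correction, switching to an exact
conditional test whenever any expected cell count falls below 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "chi_square_test",
    "fisher_exact_test",
    "two_group_anova",
    "cohort_table",
]

MANIFEST_COLUMNS = ("subject_id", "group", "age", "sex", "education")


@dataclass(frozen=True)
class ContingencyTable:
    """groups x categories count matrix with labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (c < 0).any() or c.sum() == 0:
            raise ValueError("counts must be non-negative with positive total")
        object.__setattr__(self, "counts", c)

    @property
    def expected(self) -> np.ndarray:
        c = self.counts.astype(float)
        return np.outer(c.sum(axis=1), c.sum(axis=0)) / c.sum()


def _check_margins(table: ContingencyTable) -> None:
    c = table.counts
    if (c.sum(axis=1) == 0).any() or (c.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")


def chi_square_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (chi2, df, p) with df = (rows-1)(cols-1) and p from the upper
    chi-square tail.
    """
    _check_margins(table)
    chi2, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact_test(table: ContingencyTable, max_total: int = 500) -> float:
    """Exact conditional test for an r x c table.

    Two-sided p = total probability, under the multivariate hypergeometric
    null with margins fixed, of every table at least as extreme (probability
    <= that of the observed table, within floating tolerance).  Enumerates
    all tables with the observed margins; refuses tables too large to
    enumerate and points to the chi-square test instead.
    """
    _check_margins(table)
    c = table.counts
    if c.sum() > max_total:
        raise ValueError(
            f"table total {c.sum()} > {max_total}: enumeration infeasible, use chi_square_test"
        )
    row_sums = c.sum(axis=1)
    col_sums = c.sum(axis=0)
    # log multinomial normalizer: P(table) = prod(r_i!) prod(c_j!) / (N! prod(n_ij!))
    log_const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(c.sum() + 1)

    def log_prob(tab: np.ndarray) -> float:
        return log_const - gammaln(tab + 1).sum()

    p_obs = log_prob(c)
    total = 0.0

    rows, cols = c.shape

    def recurse(i: int, remaining_cols: np.ndarray, partial: list[np.ndarray]):
        nonlocal total
        if i == rows - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            tab = np.vstack(partial + [last])
            lp = log_prob(tab)
            if lp <= p_obs + 1e-9:
                total += np.exp(lp)
            return
        for row in _rows_with_sum(remaining_cols, row_sums[i], cols):
            recurse(i + 1, remaining_cols - row, partial + [row])

    recurse(0, col_sums.copy(), [])
    return float(min(total, 1.0))


def _rows_with_sum(caps: np.ndarray, s: int, cols: int):
    """All non-negative integer rows summing to s with per-column caps."""
    row = np.zeros(cols, dtype=int)

    def gen(j: int, left: int):
        if j == cols - 1:
            if left <= caps[j]:
                row[j] = left
                yield row.copy()
            return
        for v in range(min(left, caps[j]) + 1):
            row[j] = v
            yield from gen(j + 1, left - v)

    yield from gen(0, s)


def two_group_anova(values_a, values_b) -> tuple[float, float]:
    """One-way ANOVA for two groups: F on (1, n_a + n_b - 2) df.

    Equals the square of the pooled two-sample t; p-values coincide.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    F, p = stats.f_oneway(a, b)
    if not np.isfinite(F):
        raise ValueError("degenerate data: zero within-group variance")
    return float(F), float(p)


def cohort_table(
    manifest: pd.DataFrame,
    continuous: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("sex", "education"),
    expected_cell_min: float = 5.0,
) -> pd.DataFrame:
    """Demographic comparison table from a cohort manifest.

    One row per variable level: mean +- sd per group for continuous
    variables (ANOVA p), count (within-group %) for categorical levels
    (chi-square p, or the exact test when any expected cell < 5).  Group
    sizes come from the manifest itself, never from assumptions.
    """
    required = {"group"} | set(continuous) | set(categorical)
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    groups = sorted(manifest["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    sub = {g: manifest[manifest["group"] == g] for g in groups}

    rows = []
    for var in continuous:
        F, p = two_group_anova(sub[ga][var], sub[gb][var])
        rows.append({
            "variable": var, "level": "",
            ga: f"{sub[ga][var].mean():.1f} ± {sub[ga][var].std(ddof=1):.1f}",
            gb: f"{sub[gb][var].mean():.1f} ± {sub[gb][var].std(ddof=1):.1f}",
            "test": "anova", "statistic": round(F, 4), "p_value": round(p, 4),
        })
    for var in categorical:
        levels = sorted(manifest[var].astype(str).unique())
        counts = np.array(
            [[int((sub[g][var].astype(str) == lv).sum()) for lv in levels] for g in groups]
        )
        if len(levels) < 2:
            # degenerate one-level variable (tiny cohorts): counts only, no test
            p, statistic, test_name = np.nan, np.nan, ""
        else:
            table = ContingencyTable(counts, tuple(groups), tuple(levels))
            if (table.expected < expected_cell_min).any():
                p = fisher_exact_test(table)
                test_name, statistic = "fisher_exact", np.nan
            else:
                statistic, _, p = chi_square_test(table)
                test_name = "chi_square"
        for j, lv in enumerate(levels):
            rows.append({
                "variable": var, "level": lv,
                ga: f"{counts[0, j]} ({100 * counts[0, j] / len(sub[ga]):.1f}%)",
                gb: f"{counts[1, j]} ({100 * counts[1, j] / len(sub[gb]):.1f}%)",
                "test": test_name if j == 0 else "",
                "statistic": round(statistic, 4) if j == 0 and np.isfinite(statistic) else np.nan,
                "p_value": round(p, 4) if j == 0 else np.nan,
            })
    return pd.DataFrame(rows)
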