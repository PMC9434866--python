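"""Descriptive and inferential statistics of the reference chemistry.

Two views of the biology: per-tissue Pearson correlation matrices among
the carbohydrate constituents (with two-sided t-based significance at
P < 0.05), and two-group contrasts — tapped vs control trees, tapping vs
non-tapping side — by Welch's unequal-variance t test with the usual
star codes (* <= 0.05, ** <= 0.01, *** <= 0.001).

Part–whole correlations (NSC against its own summands) are reported as
computed, without correction, matching how such tables are conventionally
presented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nircarb.errors import GroupingError, InsufficientSamplesError

DEFAULT_VARIABLES = ("glucose", "sucrose", "fructose", "starch", "nsc")


@dataclass
class CorrelationMatrix:
    """Pearson correlations with per-pair p-values and significance flags."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    n: int
    alpha: float


def correlation_matrix(
    table: pd.DataFrame,
    tissue: str | None = None,
    alpha: float = 0.05,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations within one tissue subset.

    Pairs involving a constant column get r = NaN and are flagged
    not-significant rather than raising.
    """
    sub = table if tissue is None else table[table["tissue"] == tissue]
    n = len(sub)
    if n < 3:
        raise InsufficientSamplesError(
            f"need >= 3 samples, got {n} for tissue {tissue!r}"
        )
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    data = sub[list(variables)].to_numpy(dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data[:, i], data[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    sig = np.where(np.isnan(p), False, p < alpha)
    np.fill_diagonal(sig, False)
    idx = list(variables)
    return CorrelationMatrix(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        significant=pd.DataFrame(sig.astype(bool), index=idx, columns=idx),
        n=n,
        alpha=alpha,
    )


def star_code(p: float) -> str:
    """Significance stars: *** <= 0.001, ** <= 0.01, * <= 0.05, else ''."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def group_compare(
    values: np.ndarray, groups: np.ndarray
) -> tuple[float, float, str]:
    """Welch's two-sample comparison of a constituent between two groups.

    Returns ``(t statistic, two-sided p, star code)``. Requires exactly two
    group levels with at least two observations each. Two identical
    zero-spread groups compare as (0, 1, '').
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise GroupingError(f"need exactly 2 group levels, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if a.size < 2 or b.size < 2:
        raise GroupingError("each group needs >= 2 observations")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, ""
        return np.inf, 0.0, "***"
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, star_code(p)


def correlation_table_csv(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Long-format export: one row per unordered variable pair."""
    rows = []
    for i, vi in enumerate(matrix.variables):
        for j in range(i):
            vj = matrix.variables[j]
            rows.append(
                {
                    "var1": vj,
                    "var2": vi,
                    "r": matrix.r.iloc[i, j],
                    "p": matrix.p.iloc[i, j],
                    "significant": bool(matrix.significant.iloc[i, j]),
                }
            )
    return pd.DataFrame(rows)


def treatment_contrasts(
    table: pd.DataFrame,
    group_column: str = "treatment",
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
) -> pd.DataFrame:
    """Per-(tissue, season, constituent) two-group contrast table.

    Long-format output with group means, Welch statistic, p-value and star
    code — the tabular counterpart of the boxplot-with-stars figures.
    """
    rows = []
    for (tissue, season), sub in table.groupby(["tissue", "season"]):
        levels = pd.unique(sub[group_column])
        if len(levels) != 2:
            continue
        for var in variables:
            t, p, stars = group_compare(
                sub[var].to_numpy(), sub[group_column].to_numpy()
            )
            means = sub.groupby(group_column)[var].mean()
            rows.append(
                {
                    "tissue": tissue,
                    "season": season,
                    "constituent": var,
                    "group_a": levels[0],
                    "mean_a": float(means[levels[0]]),
                    "group_b": levels[1],
                    "mean_b": float(means[levels[1]]),
                    "t": t,
                    "p": p,
                    "stars": stars,
                }
            )
    return pd.DataFrame(rows)
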