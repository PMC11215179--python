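"""Group comparison statistics: ANOVA, Bonferroni post hoc, compact letters.

Reproduces the summary-table machinery used for multi-strain phenotype
comparisons: per-group mean ± SD, a one-way ANOVA F test across groups,
all-pairs two-sample t tests with Bonferroni adjustment, and a compact
letter display (groups sharing a letter are not significantly different at
level α; the group with the largest mean receives the earliest letter).

The F statistic is computed from the classical between/within
sums-of-squares decomposition with the p value taken from the F(k−1, N−k)
distribution; pairwise tests default to pooled-variance t (the classical
Bonferroni post hoc), with a Welch option.
"""

from __future__ import annotations

import string
import warnings
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult", "summarize", "one_way_anova", "bonferroni_pairwise",
    "compact_letters", "make_table", "format_p",
]


class AnovaResult(NamedTuple):
    F: float
    p: float
    df_between: int
    df_within: int


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {str(k): np.asarray(v, dtype=np.float64) for k, v in values_by_group.items()}
    for name, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return groups


def summarize(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n−1 denominator).

    A single-observation group gets SD 0 with a warning (the n−1 rule is
    undefined there).
    """
    groups = _as_groups(values_by_group)
    rows = []
    for name, arr in groups.items():
        if arr.size == 1:
            warnings.warn(f"group {name!r} has a single observation; SD reported as 0")
            sd = 0.0
        else:
            sd = float(arr.std(ddof=1))
        rows.append({"group": name, "n": int(arr.size), "mean": float(arr.mean()), "sd": sd})
    return pd.DataFrame(rows).set_index("group")


def one_way_anova(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA across ≥ 2 groups."""
    groups = _as_groups(values_by_group)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([a.size for a in groups.values()])
    N = int(ns.sum())
    if N <= k:
        raise ValueError("total sample size must exceed the number of groups")
    means = np.array([a.mean() for a in groups.values()])
    grand = float(np.concatenate(list(groups.values())).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in groups.values()))
    dfb, dfw = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all values identical; ANOVA undefined")
        warnings.warn("zero within-group variance with unequal means; p reported as 0")
        return AnovaResult(float("inf"), 0.0, dfb, dfw)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), p, dfb, dfw)


def bonferroni_pairwise(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    method: str = "pooled",
) -> pd.DataFrame:
    """All k(k−1)/2 two-sample t tests, Bonferroni-adjusted.

    Adjusted p = min(1, raw p × number of comparisons).  ``method`` is
    "pooled" (classical) or "welch".  Returns a symmetric DataFrame with
    NaN on the diagonal.
    """
    if method not in ("pooled", "welch"):
        raise ValueError("method must be 'pooled' or 'welch'")
    groups = _as_groups(values_by_group)
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    m = k * (k - 1) // 2
    mat = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                raw = 1.0 if a.mean() == b.mean() else 0.0
            else:
                raw = float(sps.ttest_ind(a, b, equal_var=(method == "pooled")).pvalue)
            adj = min(1.0, raw * m)
            mat.iloc[i, j] = mat.iloc[j, i] = adj
    return mat


def _letter(idx: int) -> str:
    letters = string.ascii_lowercase
    out = ""
    idx += 1
    while idx > 0:
        idx, rem = divmod(idx - 1, 26)
        out = letters[rem] + out
    return out


def compact_letters(
    adjusted_p: pd.DataFrame,
    alpha: float = 0.05,
    means: Mapping[str, float] | pd.Series | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter iff their adjusted p ≥ α.  When
    ``means`` is given, groups are ranked by descending mean so the largest
    group receives the letter "a".
    """
    if adjusted_p.shape[0] != adjusted_p.shape[1]:
        raise ValueError("adjusted-p matrix must be square")
    if list(adjusted_p.index) != list(adjusted_p.columns):
        raise ValueError("adjusted-p matrix rows and columns must match")
    names = list(adjusted_p.index)
    if means is not None:
        names = sorted(names, key=lambda g: -float(means[g]))
    order = {g: i for i, g in enumerate(names)}

    columns: list[set[str]] = [set(names)]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            p = adjusted_p.loc[gi, gj]
            if np.isnan(p) or p >= alpha:
                continue
            new_cols: list[set[str]] = []
            for col in columns:
                if gi in col and gj in col:
                    new_cols.append(col - {gj})
                    new_cols.append(col - {gi})
                else:
                    new_cols.append(col)
            # absorb: drop any column that is a subset of another
            columns = [c for c in new_cols
                       if not any(c < d for d in new_cols)]
            # dedupe while keeping order
            seen: list[set[str]] = []
            for c in columns:
                if c not in seen:
                    seen.append(c)
            columns = seen
    columns.sort(key=lambda c: min(order[g] for g in c))
    assigned: dict[str, str] = {g: "" for g in names}
    for idx, col in enumerate(columns):
        for g in names:
            if g in col:
                assigned[g] += _letter(idx)
    return assigned


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p value for a summary table; values below the floor as '<0.001'."""
    return f"<{floor:g}" if p < floor else f"{p:.3f}"


def make_table(
    df: pd.DataFrame,
    group_col: str,
    feature_cols: Sequence[str] | None = None,
    alpha: float = 0.05,
    pairwise_method: str = "pooled",
) -> pd.DataFrame:
    """Summary table: one row per feature, mean ± SD with letter superscripts, F, p."""
    if group_col not in df.columns:
        raise ValueError(f"missing group column {group_col!r}")
    if df[group_col].isna().any():
        raise ValueError("missing group labels")
    if feature_cols is None:
        feature_cols = [c for c in df.columns
                        if c != group_col and pd.api.types.is_numeric_dtype(df[c])]
    if not feature_cols:
        raise ValueError("no feature columns to summarize")
    group_names = list(dict.fromkeys(df[group_col]))
    rows = []
    for feat in feature_cols:
        groups = {g: df.loc[df[group_col] == g, feat].dropna().to_numpy()
                  for g in group_names}
        groups = {g: v for g, v in groups.items() if v.size > 0}
        summ = summarize(groups)
        res = one_way_anova(groups)
        letters = compact_letters(bonferroni_pairwise(groups, alpha, pairwise_method),
                                  alpha, means=summ["mean"])
        row = {"index": feat}
        for g in groups:
            row[g] = f"{summ.loc[g, 'mean']:.2f} ± {summ.loc[g, 'sd']:.2f}^{letters[g]}^"
        row["F"] = round(res.F, 2)
        row["p"] = format_p(res.p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")
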