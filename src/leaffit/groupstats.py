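"""Group comparison of derived growth parameters.

Two groups are compared with a Student's t-test (pooled variance — the
equal-variance form; Welch is available behind a flag).  Three or more
groups get a one-way ANOVA followed by Scheffé post hoc contrasts, with
the outcome summarised as a compact letter display: groups sharing no
letter differ at the configured significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDataError

__all__ = ["ttest_two_groups", "anova_scheffe", "compact_letter_display"]


def _check_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InputDataError(f"group {name!r} needs n >= 2, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InputDataError(f"group {name!r} contains non-finite values")
    return arr


def ttest_two_groups(a, b, welch: bool = False) -> dict:
    """Two-sided Student's t-test between two groups of per-leaf values.

    Returns t, df, p and the percent difference of means,
    ``(mean_b - mean_a) / mean_a * 100`` — i.e. group ``a`` is the
    reference (control).
    """
    a = _check_group(a, "a")
    b = _check_group(b, "b")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = float(res.df)
    else:
        df = float(a.size + b.size - 2)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = np.nan if mean_a == 0 else (mean_b - mean_a) / mean_a * 100.0
    return {
        "t": float(res.statistic),
        "df": df,
        "p": float(res.pvalue),
        "percent_difference": pct,
    }


def compact_letter_display(labels, differs) -> dict:
    """Insert-and-absorb compact letter display.

    ``labels`` in display order (conventionally sorted by group mean);
    ``differs`` is a set of frozensets of label pairs that are
    significantly different.  Groups sharing no letter differ.
    """
    labels = list(labels)
    columns: list[set] = [set(labels)]
    for pair in differs:
        i, j = tuple(pair)
        for col in list(columns):
            if i in col and j in col:
                columns.remove(col)
                for drop in (i, j):
                    new = col - {drop}
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
    # absorb: drop columns that are subsets of others
    columns = [
        c for c in columns
        if not any(c < other for other in columns)
    ]
    # order columns by the first label they contain, for stable lettering
    order = {lab: k for k, lab in enumerate(labels)}
    columns.sort(key=lambda c: min(order[x] for x in c))
    letters = {lab: "" for lab in labels}
    for k, col in enumerate(columns):
        ch = chr(ord("a") + k)
        for lab in labels:
            if lab in col:
                letters[lab] += ch
    return letters


def anova_scheffe(groups: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Scheffé post hoc contrasts over >= 3 groups.

    The Scheffé statistic for a pairwise contrast is
    ``F_ij = (mean_i - mean_j)^2 / (MSE (1/n_i + 1/n_j)) / (k - 1)``,
    referred to the F(k-1, N-k) distribution — simultaneously valid over
    all contrasts, hence conservative relative to unadjusted pairwise
    tests.  Returns the overall F and p, a pairwise table, and a compact
    letter display at level ``alpha``.
    """
    if len(groups) < 3:
        raise InputDataError(
            "ANOVA + Scheffé requires >= 3 groups; use ttest_two_groups for two"
        )
    arrs = {name: _check_group(v, name) for name, v in groups.items()}
    k = len(arrs)
    n_total = sum(a.size for a in arrs.values())
    grand = np.concatenate(list(arrs.values())).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values())
    df_b, df_w = k - 1, n_total - k
    if ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    mse = ss_within / df_w if df_w > 0 else 0.0

    names = sorted(arrs, key=lambda g: arrs[g].mean())
    rows = []
    differs = set()
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            ai, aj = arrs[gi], arrs[gj]
            diff = float(aj.mean() - ai.mean())
            denom = mse * (1.0 / ai.size + 1.0 / aj.size)
            if denom == 0:
                f_ij = np.inf if diff != 0 else 0.0
            else:
                f_ij = diff**2 / denom / df_b
            p_ij = float(stats.f.sf(f_ij, df_b, df_w)) if np.isfinite(f_ij) else 0.0
            if f_ij == 0:
                p_ij = 1.0
            sig = p_ij < alpha
            if sig:
                differs.add(frozenset((gi, gj)))
            rows.append(
                {"group_1": gi, "group_2": gj, "diff": diff,
                 "F": f_ij, "p": p_ij, "significant": sig}
            )
    letters = compact_letter_display(names, differs)
    return {
        "F": float(f_stat),
        "p": float(p),
        "pairwise": pd.DataFrame(rows),
        "letters": letters,
        "alpha": alpha,
    }
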