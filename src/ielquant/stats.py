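"""Group-comparison statistics for the co-culture read-outs.

Two groups are compared with a two-tailed unpaired t test, with Welch's
correction (unequal variances, Welch-Satterthwaite degrees of freedom) as
the default variant.  Three or more groups use one-way ANOVA followed by
Sidak-adjusted pairwise comparisons (``p_adj = 1 - (1 - p)^m`` over the m
selected comparisons), with pairwise t statistics on the pooled ANOVA
error variance — the convention of common interactive stats packages.  The
significance level is 5% throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_value: float
    adjusted_p: float | None
    method: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p <= self.alpha


def _validate_sample(x, name: str):
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"sample {name!r} needs >= 2 values")
    if np.var(x, ddof=1) == 0:
        raise ValueError(f"sample {name!r} has zero variance")
    return x


def welch_t_test(a, b, alpha: float = 0.05, names=("a", "b")) -> ComparisonResult:
    """Two-tailed unequal-variance t test (Welch-Satterthwaite df)."""
    a = _validate_sample(a, names[0])
    b = _validate_sample(b, names[1])
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        group_a=names[0], group_b=names[1],
        statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue), adjusted_p=None,
        method="welch_t", alpha=alpha,
    )


def student_t_test(a, b, alpha: float = 0.05, names=("a", "b")) -> ComparisonResult:
    """Two-tailed equal-variance (pooled) t test."""
    a = _validate_sample(a, names[0])
    b = _validate_sample(b, names[1])
    res = sps.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        group_a=names[0], group_b=names[1],
        statistic=float(res.statistic), df=float(len(a) + len(b) - 2),
        p_value=float(res.pvalue), adjusted_p=None,
        method="student_t", alpha=alpha,
    )


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment over m comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def anova_sidak(
    groups,
    labels=None,
    comparisons=None,
    alpha: float = 0.05,
    pairwise: str = "pooled",
) -> list[ComparisonResult]:
    """One-way ANOVA with Sidak-adjusted post-hoc pairwise comparisons.

    Parameters
    ----------
    groups : sequence of >= 3 numeric samples (each with >= 2 values).
    labels : group names (defaults to g0, g1, ...).
    comparisons : pairs of labels forming the Sidak family; defaults to
        all pairwise comparisons.
    pairwise : "pooled" (t on the pooled ANOVA error variance, df = N - k;
        the convention of common interactive packages) or "welch".

    Returns the omnibus F result first, then one ComparisonResult per
    selected pair with ``adjusted_p = 1 - (1 - p)^m``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("anova_sidak needs >= 3 groups; use welch_t_test / student_t_test for 2")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    for g, lab in zip(groups, labels):
        _validate_sample(g, lab)
    by_label = dict(zip(labels, groups))

    f_stat, f_p = sps.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    df_error = n_total - k
    mse = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df_error

    results = [
        ComparisonResult(
            group_a="omnibus", group_b="omnibus",
            statistic=float(f_stat), df=float(df_error),
            p_value=float(f_p), adjusted_p=None,
            method="anova", alpha=alpha,
        )
    ]
    pairs = list(comparisons) if comparisons is not None else list(combinations(labels, 2))
    m = len(pairs)
    for la, lb in pairs:
        ga, gb = by_label[la], by_label[lb]
        if pairwise == "pooled":
            se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
            t = (np.mean(ga) - np.mean(gb)) / se
            df = float(df_error)
            p = 2.0 * sps.t.sf(abs(t), df)
        elif pairwise == "welch":
            r = sps.ttest_ind(ga, gb, equal_var=False)
            t, df, p = float(r.statistic), float(r.df), float(r.pvalue)
        else:
            raise ValueError("pairwise must be 'pooled' or 'welch'")
        results.append(
            ComparisonResult(
                group_a=la, group_b=lb,
                statistic=float(t), df=df, p_value=float(p),
                adjusted_p=sidak_adjust(float(p), m),
                method="anova_sidak", alpha=alpha,
            )
        )
    return results


def compare_groups(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    design: str = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long-format entry point: Welch t for two groups, ANOVA + Sidak for
    three or more (``design='auto'``); returns a tidy comparison table."""
    labels = list(pd.unique(df[group]))
    samples = [df.loc[df[group] == lab, value].to_numpy() for lab in labels]
    if design == "auto":
        design = "pairs" if len(labels) == 2 else "anova"
    if design == "pairs":
        if len(labels) != 2:
            raise ValueError("design='pairs' requires exactly 2 groups")
        results = [welch_t_test(samples[0], samples[1], alpha=alpha, names=tuple(labels))]
    elif design == "anova":
        results = anova_sidak(samples, labels=labels, alpha=alpha)
    else:
        raise ValueError("design must be 'auto', 'pairs' or 'anova'")
    return pd.DataFrame([r.__dict__ for r in results])
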