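"""Group comparisons of morphology tables.

Descriptives are mean ± SD (n−1 denominator).  Two groups are compared with
an unpaired two-sided t-test (pooled variance by default — the classic
companion of ANOVA + Tukey under homoscedasticity — with Welch available by
flag); three or more groups with a one-way ANOVA F-test followed by Tukey's
HSD, whose adjusted p-values come from the studentized-range distribution.
Significance is declared at p < alpha (strict), default alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class TukeyPair:
    pair: Tuple[str, str]
    mean_diff: float
    p_adj: float


@dataclass
class GroupComparison:
    metric_name: str
    groups: List[GroupSummary]
    test: str                    # "t_test" | "anova"
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    tukey: Optional[List[TukeyPair]] = None
    degenerate: bool = False     # zero within-group variance everywhere


def _extract_groups(
    table: pd.DataFrame, metric_name: str, group_col: str
) -> Tuple[List[str], List[np.ndarray]]:
    labels, samples = [], []
    for label, sub in table.groupby(group_col, sort=True):
        vals = pd.to_numeric(sub[metric_name], errors="coerce").dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(
                f"group {label!r} has {len(vals)} finite values of "
                f"{metric_name!r}; need at least 2"
            )
        labels.append(str(label))
        samples.append(vals)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    return labels, samples


def compare_groups(
    table: pd.DataFrame,
    metric_name: str,
    group_col: str = "group",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare one metric across the groups of a records table.

    Missing values are dropped per group.  Two groups get an unpaired
    t-test (pooled unless ``equal_var=False``); three or more get one-way
    ANOVA plus Tukey HSD over all pairs.
    """
    labels, samples = _extract_groups(table, metric_name, group_col)
    summaries = [
        GroupSummary(label=lbl, n=len(v), mean=float(np.mean(v)),
                     sd=float(np.std(v, ddof=1)))
        for lbl, v in zip(labels, samples)
    ]
    degenerate = all(np.var(v) == 0 for v in samples)
    if degenerate:
        means = [float(np.mean(v)) for v in samples]
        if len(set(means)) > 1:
            stat, p = float("inf"), 0.0
        else:
            stat, p = 0.0, 1.0
        test = "t_test" if len(samples) == 2 else "anova"
        return GroupComparison(
            metric_name=metric_name, groups=summaries, test=test,
            statistic=stat, p_value=p, significant=p < alpha, alpha=alpha,
            degenerate=True,
        )
    if len(samples) == 2:
        t, p = sps.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        return GroupComparison(
            metric_name=metric_name, groups=summaries, test="t_test",
            statistic=float(t), p_value=float(p),
            significant=float(p) < alpha, alpha=alpha,
        )
    f, p = sps.f_oneway(*samples)
    res = sps.tukey_hsd(*samples)
    pairs = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            pairs.append(
                TukeyPair(
                    pair=(labels[i], labels[j]),
                    mean_diff=float(np.mean(samples[i]) - np.mean(samples[j])),
                    p_adj=float(res.pvalue[i, j]),
                )
            )
    return GroupComparison(
        metric_name=metric_name, groups=summaries, test="anova",
        statistic=float(f), p_value=float(p),
        significant=float(p) < alpha, alpha=alpha, tukey=pairs,
    )


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons to one row per metric for CSV export."""
    rows = []
    for c in comparisons:
        row = {
            "metric": c.metric_name,
            "test": c.test,
            "statistic": c.statistic,
            "p_value": c.p_value,
            "significant": c.significant,
            "degenerate": c.degenerate,
        }
        for g in c.groups:
            row[f"mean_{g.label}"] = g.mean
            row[f"sd_{g.label}"] = g.sd
            row[f"n_{g.label}"] = g.n
        if c.tukey:
            for t in c.tukey:
                row[f"tukey_p[{t.pair[0]} vs {t.pair[1]}]"] = t.p_adj
        rows.append(row)
    return pd.DataFrame(rows)


def significance_summary(comparisons: Sequence[GroupComparison]) -> str:
    """Plain-text report of which metrics differ between groups."""
    lines = []
    for c in comparisons:
        verdict = "significant" if c.significant else "not significant"
        desc = ", ".join(f"{g.label}: {g.mean:.4g} ± {g.sd:.4g} (n={g.n})"
                         for g in c.groups)
        lines.append(
            f"{c.metric_name}: {c.test} p={c.p_value:.4g} ({verdict} at "
            f"alpha={c.alpha}); {desc}"
        )
        if c.tukey:
            for t in c.tukey:
                mark = "*" if t.p_adj < c.alpha else " "
                lines.append(
                    f"  {mark} {t.pair[0]} vs {t.pair[1]}: diff="
                    f"{t.mean_diff:.4g}, p_adj={t.p_adj:.4g}"
                )
    return "\n".join(lines)
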