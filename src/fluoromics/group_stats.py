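"""Group comparison utilities: one-way ANOVA followed by Fisher's LSD.

Replicated phenotyping parameters (JIP-test values, quenching fits) are
conventionally summarised as group mean ± SE with compact letter display:
groups sharing a letter are not significantly different by the LSD test at
the chosen alpha.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["anova_lsd", "GroupComparison"]


@dataclass
class GroupComparison:
    """One-way ANOVA plus pairwise-LSD summary for one response variable."""

    f_statistic: float
    p_value: float
    summary: pd.DataFrame          # index group; columns mean, se, n, letters
    pairwise: pd.DataFrame         # columns group1, group2, diff, p


def _letters(groups: list[str], means: dict[str, float], distinct: set[frozenset]) -> dict[str, str]:
    """Compact letter display by the insertion method (largest mean first)."""
    order = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []          # groups sharing each letter
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) not in distinct for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def anova_lsd(values: pd.Series, groups: pd.Series, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    ``values`` and ``groups`` are aligned observation-level series.  The
    LSD test uses the pooled ANOVA mean-square error, t-distributed on the
    residual degrees of freedom.  Groups need >= 2 replicates each.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).reindex(values.index)
    by = {g: values[groups == g].values for g in sorted(groups.dropna().unique())}
    if len(by) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(v) < 2 for v in by.values()):
        raise ValidationError("each group needs at least 2 replicates")

    names = list(by)
    f_stat, p_val = stats.f_oneway(*by.values())
    n_total = sum(len(v) for v in by.values())
    df_err = n_total - len(by)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / df_err

    rows = []
    distinct: set[frozenset] = set()
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            v1, v2 = by[g1], by[g2]
            diff = v1.mean() - v2.mean()
            se = np.sqrt(mse * (1 / len(v1) + 1 / len(v2)))
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            p = 2 * stats.t.sf(abs(t), df_err)
            rows.append((g1, g2, diff, p))
            if p < alpha:
                distinct.add(frozenset((g1, g2)))
    means = {g: float(v.mean()) for g, v in by.items()}
    letters = _letters(names, means, distinct)
    summary = pd.DataFrame(
        {
            "mean": [means[g] for g in names],
            "se": [by[g].std(ddof=1) / np.sqrt(len(by[g])) for g in names],
            "n": [len(by[g]) for g in names],
            "letters": [letters[g] for g in names],
        },
        index=pd.Index(names, name="group"),
    )
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "diff", "p"])
    return GroupComparison(f_statistic=float(f_stat), p_value=float(p_val),
                           summary=summary, pairwise=pairwise)
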