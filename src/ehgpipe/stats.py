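"""One-way ANOVA with Tukey HSD across segment positions.

Compares a performance metric (typically sensitivity) between positional
windows of the same duration. Replicates are independent training runs
(different seeds); a per-fold mode simply means the caller passes per-fold
values instead. The omnibus F-test is delegated to scipy and the pairwise
Tukey honestly-significant-difference comparisons to statsmodels; both are
routine statistics verified against the closed-form F on fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["PositionSEGroups", "AnovaTukeyResult", "anova_tukey"]


@dataclass
class PositionSEGroups:
    """Metric replicates per window label; values are proportions in [0, 1]."""

    groups: dict[str, list[float]]

    def __post_init__(self) -> None:
        for label, vals in self.groups.items():
            if len(vals) < 2:
                raise ValueError(f"group {label!r} needs >= 2 replicates, got {len(vals)}")
            if any(not (0 <= v <= 1) for v in vals):
                raise ValueError(f"group {label!r} has values outside [0, 1]")


@dataclass
class AnovaTukeyResult:
    omnibus_p: float
    f_statistic: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, significant
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group1"], sig["group2"]))


def anova_tukey(groups: PositionSEGroups | dict, alpha: float = 0.05) -> AnovaTukeyResult:
    """Omnibus one-way ANOVA + Tukey HSD pairwise table.

    Fully degenerate input (all groups constant and equal) takes the
    p = 1 / nothing-significant path rather than erroring.
    """
    if isinstance(groups, dict):
        groups = PositionSEGroups(groups)
    if len(groups.groups) < 2:
        raise ValueError("need at least two groups to compare")
    labels = sorted(groups.groups)
    arrays = [np.asarray(groups.groups[lab], dtype=float) for lab in labels]

    values = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        # zero within-group variance: identical groups are indistinguishable
        # (p=1); groups with different means are separated with certainty
        pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        diffs = [arrays[j].mean() - arrays[i].mean() for i, j in pairs]
        table = pd.DataFrame(
            dict(
                group1=[labels[i] for i, _ in pairs],
                group2=[labels[j] for _, j in pairs],
                meandiff=diffs,
                p_adj=[1.0 if d == 0 else 0.0 for d in diffs],
                significant=[d != 0 for d in diffs],
            )
        )
        degenerate = np.ptp(values) == 0
        return AnovaTukeyResult(
            omnibus_p=1.0 if degenerate else 0.0,
            f_statistic=0.0 if degenerate else float("inf"),
            pairwise=table,
            alpha=alpha,
        )

    f_stat, p = sstats.f_oneway(*arrays)
    if not np.isfinite(p):
        p, f_stat = 1.0, 0.0

    flat_labels = np.concatenate([[lab] * len(arr) for lab, arr in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, flat_labels, alpha=alpha)
    table = pd.DataFrame(
        dict(
            group1=[str(g) for g in tukey.groupsunique[tukey._multicomp.pairindices[0]]],
            group2=[str(g) for g in tukey.groupsunique[tukey._multicomp.pairindices[1]]],
            meandiff=tukey.meandiffs,
            p_adj=tukey.pvalues,
            significant=tukey.reject,
        )
    )
    return AnovaTukeyResult(
        omnibus_p=float(p), f_statistic=float(f_stat), pairwise=table, alpha=alpha
    )
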