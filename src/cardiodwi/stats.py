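"""Group comparison with distribution-aware test selection, and correlation.

Mirrors the common clinical-statistics workflow: Shapiro-Wilk normality on
each group decides between parametric (Welch t for two groups, one-way
ANOVA for more) and nonparametric (Mann-Whitney U, Kruskal-Wallis)
comparisons, all two-sided at alpha = 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "pearson_correlation"]


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a multi-group comparison."""

    names: tuple
    n: tuple
    means: tuple
    sds: tuple
    test: str  # "t" | "mann-whitney" | "anova" | "kruskal-wallis"
    statistic: float
    p_value: float
    alpha: float
    normal: bool

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(samples: Sequence[Sequence[float]], alpha: float = 0.05,
                   names: Sequence[str] | None = None) -> GroupComparison:
    """Compare >= 2 groups with normality-driven test selection.

    Each group needs n >= 3 (the Shapiro-Wilk minimum).  If every group
    passes Shapiro-Wilk at ``alpha``, a parametric test is used: Welch's
    unequal-variance t-test for two groups, one-way ANOVA otherwise.
    Any non-normal group switches to Mann-Whitney U / Kruskal-Wallis.
    All tests are two-sided.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    for g in groups:
        if g.size < 3:
            raise ValueError("every group needs n >= 3")
    if names is None:
        names = tuple(f"group_{i + 1}" for i in range(len(groups)))

    # constant groups make Shapiro degenerate; treat them as non-normal
    normal = True
    for g in groups:
        if np.ptp(g) == 0:
            normal = False
            break
        if sps.shapiro(g).pvalue <= alpha:
            normal = False
            break

    if len(groups) == 2:
        if normal:
            res = sps.ttest_ind(*groups, equal_var=False)
            test = "t"
        else:
            res = sps.mannwhitneyu(*groups, alternative="two-sided")
            test = "mann-whitney"
    else:
        if normal:
            res = sps.f_oneway(*groups)
            test = "anova"
        else:
            res = sps.kruskal(*groups)
            test = "kruskal-wallis"

    return GroupComparison(
        names=tuple(names),
        n=tuple(int(g.size) for g in groups),
        means=tuple(float(g.mean()) for g in groups),
        sds=tuple(float(g.std(ddof=1)) for g in groups),
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        normal=normal,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Requires equal lengths >= 3 and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
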