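"""Group-comparison statistics used throughout the analyses.

Conventions: the rank-sum statistic W reported here is the Mann-Whitney U
of the first-named group (the convention of R's ``wilcox.test``, so values
are directly comparable with the field's reported W statistics); medians
accompany every test to fix the direction.  Pairwise tests after an omnibus
Kruskal-Wallis are Bonferroni-corrected; families of per-feature p-values
(the MALDI peak screen) use Benjamini-Hochberg instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "RankSumResult",
    "rank_sum",
    "GroupComparison",
    "compare_groups",
    "AnovaResult",
    "interaction_anova",
    "bh_adjust",
    "bonferroni_adjust",
    "min_attainable_p",
]


@dataclass
class RankSumResult:
    statistic_w: float      # Mann-Whitney U of the first group
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float

    @property
    def direction(self) -> str:
        if self.median1 > self.median2:
            return "higher"
        if self.median1 < self.median2:
            return "lower"
        return "tied"


def rank_sum(x, y) -> RankSumResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null distribution for small tie-free samples, midrank/normal
    approximation with continuity correction otherwise (scipy's ``auto``
    policy, which switches at n = 8 or in the presence of ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise DataError("both groups must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return RankSumResult(statistic_w=float(res.statistic), p_value=float(res.pvalue),
                         n1=x.size, n2=y.size,
                         median1=float(np.median(x)), median2=float(np.median(y)))


@dataclass
class GroupComparison:
    """Omnibus + post-hoc report for >= 2 groups."""

    test: str                       # "rank_sum" | "kruskal_wallis"
    statistic: float
    df: int | None
    p_value: float
    group_medians: dict[str, float]
    pairwise: dict[tuple[str, str], RankSumResult] = field(default_factory=dict)
    pairwise_p_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    flagged_groups: list[str] = field(default_factory=list)


def compare_groups(samples: dict[str, np.ndarray]) -> GroupComparison:
    """Rank-sum for two groups; Kruskal-Wallis plus Bonferroni-corrected
    pairwise rank-sum tests for three or more."""
    if len(samples) < 2:
        raise DataError("need at least two groups")
    names = list(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    flagged = [k for k, v in arrays.items() if v.size < 2]
    medians = {k: float(np.median(v)) if v.size else float("nan")
               for k, v in arrays.items()}

    if len(names) == 2:
        r = rank_sum(arrays[names[0]], arrays[names[1]])
        return GroupComparison(test="rank_sum", statistic=r.statistic_w, df=None,
                               p_value=r.p_value, group_medians=medians,
                               pairwise={(names[0], names[1]): r},
                               pairwise_p_adjusted={(names[0], names[1]): r.p_value},
                               flagged_groups=flagged)

    h, p = sps.kruskal(*arrays.values())
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    pairwise = {(a, b): rank_sum(arrays[a], arrays[b]) for a, b in pairs}
    m = len(pairs)
    adjusted = {k: min(1.0, v.p_value * m) for k, v in pairwise.items()}
    return GroupComparison(test="kruskal_wallis", statistic=float(h),
                           df=len(names) - 1, p_value=float(p),
                           group_medians=medians, pairwise=pairwise,
                           pairwise_p_adjusted=adjusted, flagged_groups=flagged)


@dataclass
class AnovaResult:
    f_treatment: float
    p_treatment: float
    f_frequency: float
    p_frequency: float
    f_interaction: float
    p_interaction: float
    table: pd.DataFrame


def interaction_anova(data: pd.DataFrame, value: str = "gain",
                      treatment: str = "treatment",
                      frequency: str = "frequency") -> AnovaResult:
    """Two-way fixed-factor ANOVA with interaction.

    ``treatment`` (disturbed vs unperturbed) x ``frequency`` (trigger
    interval); whether rebound depends on trigger frequency is read off the
    interaction term.  Empty cells are an error.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    for col in (value, treatment, frequency):
        if col not in data.columns:
            raise DataError(f"missing column {col!r}")
    cells = data.groupby([treatment, frequency], observed=True).size()
    n_t = data[treatment].nunique()
    n_f = data[frequency].nunique()
    if n_t < 2 or n_f < 2:
        raise DataError("both factors need at least two levels")
    if len(cells) < n_t * n_f or (cells < 2).any():
        raise DataError("every treatment x frequency cell needs >= 2 observations")

    df = data.rename(columns={value: "_y", treatment: "_t", frequency: "_f"})
    model = smf.ols("_y ~ C(_t) * C(_f)", data=df).fit()
    tab = anova_lm(model, typ=2)
    return AnovaResult(
        f_treatment=float(tab.loc["C(_t)", "F"]),
        p_treatment=float(tab.loc["C(_t)", "PR(>F)"]),
        f_frequency=float(tab.loc["C(_f)", "F"]),
        p_frequency=float(tab.loc["C(_f)", "PR(>F)"]),
        f_interaction=float(tab.loc["C(_t):C(_f)", "F"]),
        p_interaction=float(tab.loc["C(_t):C(_f)", "PR(>F)"]),
        table=tab,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * p.size)


def min_attainable_p(n1: int, n2: int) -> float:
    """Smallest two-sided p an exact rank-sum test can produce at (n1, n2).

    With tiny section counts this floor limits which peaks can ever reach
    significance; the screen reports it as QC.
    """
    from math import comb
    return min(1.0, 2.0 / comb(n1 + n2, n1))
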