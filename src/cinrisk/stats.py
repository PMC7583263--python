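"""Descriptive statistical battery for group comparisons.

Dispatch mirrors common clinical-genomics practice: two groups get a
Mann-Whitney U test; three or more get a variance-homogeneity gate (Levene,
mean-centred) choosing between classic one-way ANOVA with Tukey HSD and
Welch-corrected ANOVA with Games-Howell post hoc tests.  No multiplicity
correction is applied; p values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["ComparisonResult", "compare_k_groups", "mann_whitney",
           "pearson_corr", "paired_t", "chi_square"]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p: float
    details: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p={self.p} outside [0, 1]")


def mann_whitney(x, y, exact_max_n: int = 20) -> ComparisonResult:
    """Two-sided Mann-Whitney U; exact p for small samples, else the
    tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = max(x.size, y.size) <= exact_max_n and not has_ties
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(test=f"mann-whitney ({method})",
                            statistic=float(res.statistic),
                            p=float(min(res.pvalue, 1.0)))


def compare_k_groups(groups: list, levene_alpha: float = 0.05,
                     levene_center: str = "mean") -> ComparisonResult:
    """Omnibus comparison of k groups with a variance-homogeneity gate.

    k = 2 dispatches to :func:`mann_whitney`.  For k >= 3 a Levene test at
    *levene_alpha* chooses between one-way ANOVA (+ Tukey HSD) and Welch
    ANOVA (+ Games-Howell); ``details['path']`` records which fired.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        return mann_whitney(groups[0], groups[1])
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations for variance tests")

    lev_stat, lev_p = stats.levene(*groups, center=levene_center)
    long = pd.DataFrame({
        "value": np.concatenate(groups),
        "group": np.concatenate([np.full(g.size, f"g{i}") for i, g in enumerate(groups)]),
    })
    if lev_p < levene_alpha:
        aov = pg.welch_anova(data=long, dv="value", between="group")
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        posthoc = gh.rename(columns={"pval": "p"})[["A", "B", "diff", "p"]]
        return ComparisonResult(
            test="welch-anova", statistic=float(aov["F"].iloc[0]),
            p=float(aov["p_unc"].iloc[0]),
            details={"path": "heterogeneous", "levene_stat": float(lev_stat),
                     "levene_p": float(lev_p), "posthoc": "games-howell"},
            posthoc=posthoc,
        )
    f_stat, f_p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(long["value"], long["group"])
    posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    posthoc = posthoc.rename(columns={"group1": "A", "group2": "B",
                                      "meandiff": "diff", "p-adj": "p"})
    return ComparisonResult(
        test="one-way-anova", statistic=float(f_stat), p=float(f_p),
        details={"path": "homogeneous", "levene_stat": float(lev_stat),
                 "levene_p": float(lev_p), "posthoc": "tukey-hsd"},
        posthoc=posthoc[["A", "B", "diff", "p"]],
    )


def pearson_corr(x, y) -> tuple[float, float, float]:
    """Pearson r, R-squared and the two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need aligned vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def paired_t(x_pre, x_post) -> ComparisonResult:
    """Two-sided paired t test on matched samples."""
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.size != x_post.size or x_pre.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    diff = x_post - x_pre
    if np.std(diff, ddof=1) == 0:
        if diff.any():
            raise ValueError("zero-variance non-zero differences: t undefined")
        # identical samples: no change, by convention t = 0, p = 1
        return ComparisonResult(test="paired-t", statistic=0.0, p=1.0)
    t, p = stats.ttest_rel(x_post, x_pre)
    return ComparisonResult(test="paired-t", statistic=float(t), p=float(p))


def chi_square(table) -> ComparisonResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return ComparisonResult(test="pearson-chi2", statistic=float(stat),
                            p=float(p), details={"dof": int(dof)})
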