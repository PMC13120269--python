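"""Group comparisons, correlations, and reproducibility statistics.

The module defaults to the nonparametric branch (Mann-Whitney U,
Kruskal-Wallis, Spearman) with median/IQR summaries, since positive,
right-skewed ADC metrics are the input; a parametric opt-in exists for
two-group comparison.  Missing values are dropped pairwise.  Bonferroni
correction is applied only inside a post-hoc family of pairwise tests, never
globally across metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)


@dataclass
class GroupComparison:
    metric: str
    group_labels: list
    medians: list[float]
    iqrs: list[tuple[float, float]]
    test: str                      # mann-whitney / kruskal-wallis / t-test / ...
    statistic: float
    p_value: float
    post_hoc: list[tuple[tuple, float]] | None = None  # (pair, adjusted p)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n_used: int


@dataclass
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def _clean_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values) & (pd.notna(labels))
    return values[keep], labels[keep]


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (float(np.percentile(x, 25)),
                                 float(np.percentile(x, 75)))


def compare_two_groups(
    values,
    labels,
    metric: str = "",
    parametric: bool = False,
) -> GroupComparison:
    """Two-sided Mann-Whitney U (default) or Welch t-test between two groups.

    The U test uses exact enumeration when both groups have n <= 8 and no
    ties across groups, and the normal approximation with continuity
    correction otherwise (mid-ranks handle ties).
    """
    values, labels = _clean_groups(values, labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise InsufficientDataError(
            f"need exactly two non-empty groups, got labels {list(uniq)}"
        )
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("a group is empty after missing removal")
    if parametric:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        test = "t-test"
    else:
        no_ties = len(np.unique(values)) == len(values)
        method = "exact" if (max(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        stat, p = res.statistic, res.pvalue
        test = "mann-whitney"
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    return GroupComparison(
        metric=metric,
        group_labels=list(uniq),
        medians=[med_a, med_b],
        iqrs=[iqr_a, iqr_b],
        test=test,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
    )


def compare_k_groups(values, labels, metric: str = "",
                     alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis H over k >= 3 groups, with Bonferroni-adjusted pairwise
    Mann-Whitney post-hoc tests gated on overall p < alpha."""
    values, labels = _clean_groups(values, labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 3:
        raise InsufficientDataError(f"need >= 3 groups, got {len(uniq)}")
    groups = [values[labels == g] for g in uniq]
    if any(len(g) == 0 for g in groups):
        raise InsufficientDataError("a group is empty after missing removal")
    if len(np.unique(values)) == 1:
        # every observation identical: H = 0 by convention, no evidence
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups)
    post_hoc = None
    if p < alpha:
        pairs = [(uniq[i], uniq[j]) for i in range(len(uniq))
                 for j in range(i + 1, len(uniq))]
        post_hoc = []
        for ga, gb in pairs:
            res = stats.mannwhitneyu(values[labels == ga], values[labels == gb],
                                     alternative="two-sided")
            post_hoc.append(((ga, gb), float(min(1.0, res.pvalue * len(pairs)))))
    med_iqr = [_median_iqr(g) for g in groups]
    return GroupComparison(
        metric=metric,
        group_labels=uniq,
        medians=[m for m, _ in med_iqr],
        iqrs=[q for _, q in med_iqr],
        test="kruskal-wallis",
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        post_hoc=post_hoc,
    )


def spearman(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Mid-rank Spearman correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(pair=pair, rho=float(rho), p_value=float(p),
                             n_used=int(len(x)))


def compare_categorical(table) -> tuple[str, float, float]:
    """Chi-square (or Fisher's exact for sparse 2x2) association test on a
    contingency table; returns (test_name, statistic, p)."""
    table = np.asarray(table)
    if table.ndim != 2 or (table < 0).any():
        raise ValidationError("contingency table must be 2D and non-negative")
    _, _, _, expected = stats.chi2_contingency(table)
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(table)
        return "fisher", float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table)
    return "chi-square", float(chi2), float(p)


def icc_absolute(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects x raters matrix with no missing cells.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValidationError("ratings must be a subjects x raters matrix")
    n, k = ratings.shape
    if k < 2:
        raise ValidationError("need at least 2 raters")
    if n < 5:
        raise ValidationError("need at least 5 subjects")
    if not np.isfinite(ratings).all():
        raise ValidationError("missing cells are not allowed in the ICC design")
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": ratings.ravel(),
    })
    import warnings as _warnings
    with _warnings.catch_warnings():
        # degenerate designs (mse = 0 under perfect agreement) trip pingouin's
        # internal F-statistic division; the ICC itself is still well defined
        _warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                                   ratings="score")
    hit = table["Type"].isin(["ICC2", "ICC(A,1)"])
    icc2 = float(table.loc[hit, "ICC"].iloc[0])
    return ICCResult(icc=icc2, model="two-way random, absolute agreement, single",
                     n_subjects=n, n_raters=k)
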