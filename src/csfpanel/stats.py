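"""Nonparametric statistical battery for CSF peptide group comparisons.

The cohort analysis relies on rank-based tests throughout: Mann-Whitney U for
two-group peptide comparisons, Kruskal-Wallis with Dunn's post hoc for
three-or-more-group demographics, a Quade-style rank analysis of covariance
(values and covariate are ranked over the pooled sample, value ranks are
regressed on covariate ranks, and the residuals enter a one-way ANOVA) for
age-adjusted group comparisons, Spearman correlation for peptide-age and
peptide-clinical-score relations, Pearson chi-squared for sex tables, and the
rank (Mann-Whitney) formulation of the ROC area under the curve for
single-peptide diagnostic accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatTestResult",
    "RankAncovaResult",
    "CorrelationResult",
    "RocResult",
    "mann_whitney",
    "rank_ancova",
    "kruskal_dunn",
    "spearman",
    "chi_squared",
    "roc_auc",
    "bonferroni_adjust",
]


@dataclass
class StatTestResult:
    method: str
    statistic: float
    p_raw: float
    comparison: str = ""
    df: float | None = None
    p_adjusted: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.p_adjusted is not None:
            if self.p_adjusted + 1e-12 < self.p_raw:
                raise ValueError("adjusted p below raw p")


@dataclass
class RankAncovaResult:
    statistic: float
    df: tuple[int, int]
    p_omnibus: float
    pairwise: list[StatTestResult] = field(default_factory=list)
    covariate: str = "age"
    degenerate: bool = False


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class RocResult:
    auc: float
    positive_group: object
    n_pos: int
    n_neg: int


def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name}: empty sample")
    if np.isnan(arr).any():
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError(f"{name}: all values missing")
    return arr


def mann_whitney(a, b, mode: str = "auto") -> StatTestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates the null distribution (ties not supported by
    the exact path), ``'normal_approx'`` uses the tie-corrected normal
    approximation with continuity correction, and ``'auto'`` picks exact for
    tie-free samples with at most 10 observations per group, the approximation
    otherwise.
    """
    a = _as_clean_array(a, "a")
    b = _as_clean_array(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return StatTestResult(
        method=f"mann_whitney[{method}]",
        statistic=float(res.statistic),
        p_raw=float(min(res.pvalue, 1.0)),
    )


def _quade_residuals(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of value mid-ranks regressed on covariate mid-ranks."""
    rv = sps.rankdata(values)
    rc = sps.rankdata(covariate)
    rc_c = rc - rc.mean()
    denom = float(rc_c @ rc_c)
    slope = float(rc_c @ (rv - rv.mean())) / denom if denom > 0 else 0.0
    return (rv - rv.mean()) - slope * rc_c


def rank_ancova(values, groups, covariate, covariate_name: str = "age",
                posthoc: bool = True) -> RankAncovaResult:
    """Quade-style rank analysis of covariance.

    Values and the covariate are converted to mid-ranks over the pooled
    sample, value ranks are adjusted for covariate ranks by least squares, and
    the residuals are compared across groups with a one-way ANOVA F on
    (k-1, N-k) degrees of freedom. Pairwise comparisons repeat the procedure
    per group pair with Bonferroni correction over the number of pairs.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    groups = np.asarray(groups)
    mask = ~(np.isnan(values) | np.isnan(covariate))
    values, covariate, groups = values[mask], covariate[mask], groups[mask]
    labels = [g for g in dict.fromkeys(groups.tolist())]
    k = len(labels)
    if k < 2:
        raise ValueError("rank_ancova requires >= 2 groups")
    for g in labels:
        if int((groups == g).sum()) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    n = len(values)
    resid = _quade_residuals(values, covariate)
    parts = [resid[groups == g] for g in labels]
    if np.allclose(resid, 0.0):
        # constant values (or values fully determined by the covariate ranks)
        return RankAncovaResult(statistic=0.0, df=(k - 1, n - k), p_omnibus=1.0,
                                covariate=covariate_name, degenerate=True)
    f_res = sps.f_oneway(*parts)
    pairwise: list[StatTestResult] = []
    if posthoc and k > 2:
        pairs = [(labels[i], labels[j]) for i in range(k) for j in range(i + 1, k)]
        m = len(pairs)
        for ga, gb in pairs:
            sel = (groups == ga) | (groups == gb)
            r = _quade_residuals(values[sel], covariate[sel])
            sub = groups[sel]
            if np.allclose(r, 0.0):
                pairwise.append(StatTestResult("rank_ancova_pair", 0.0, 1.0,
                                               f"{ga} vs {gb}", p_adjusted=1.0,
                                               degenerate=True))
                continue
            fr = sps.f_oneway(r[sub == ga], r[sub == gb])
            p = float(min(fr.pvalue, 1.0))
            pairwise.append(StatTestResult(
                "rank_ancova_pair", float(fr.statistic), p, f"{ga} vs {gb}",
                df=float(sel.sum() - 2), p_adjusted=min(1.0, m * p)))
    return RankAncovaResult(
        statistic=float(f_res.statistic), df=(k - 1, n - k),
        p_omnibus=float(min(f_res.pvalue, 1.0)),
        pairwise=pairwise, covariate=covariate_name)


def kruskal_dunn(values, groups) -> tuple[StatTestResult, list[StatTestResult]]:
    """Tie-corrected Kruskal-Wallis omnibus with Dunn's pairwise post hoc.

    Dunn z statistics use the pooled mid-ranks and the standard tie-corrected
    variance; pairwise p values are Bonferroni-multiplied by the number of
    pairs, capped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = ~np.isnan(values)
    values, groups = values[mask], groups[mask]
    labels = [g for g in dict.fromkeys(groups.tolist())]
    k = len(labels)
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if k == 2:
        res = mann_whitney(samples[0], samples[1])
        return res, []
    h, p = sps.kruskal(*samples)
    omnibus = StatTestResult("kruskal_wallis", float(h), float(p), df=float(k - 1))
    n = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    out: list[StatTestResult] = []
    for i, j in pairs:
        ni, nj = len(samples[i]), len(samples[j])
        ri = ranks[groups == labels[i]].mean()
        rj = ranks[groups == labels[j]].mean()
        var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (1.0 / ni + 1.0 / nj)
        z = (ri - rj) / math.sqrt(var) if var > 0 else 0.0
        praw = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
        out.append(StatTestResult("dunn", float(z), praw,
                                  f"{labels[i]} vs {labels[j]}",
                                  p_adjusted=min(1.0, m * praw)))
    return omnibus, out


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation on paired complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("spearman requires >= 3 paired complete observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(rho=float("nan"), p=float("nan"), n=len(x),
                                 degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(x))


def chi_squared(table) -> StatTestResult:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() <= 0:
        raise ValueError("table total must be positive")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return StatTestResult("chi_squared", float(stat), float(p), df=float(df))


def roc_auc(scores, labels, positive_group, auto_orient: bool = False) -> RocResult:
    """ROC area under the curve by the rank (Mann-Whitney) formulation.

    AUC is the probability that a random member of the positive group scores
    higher than a random member of the negative group; tied scores contribute
    one half. With ``auto_orient`` the larger of (auc, 1-auc) is reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    mask = ~np.isnan(scores)
    scores, labels = scores[mask], labels[mask]
    pos = labels == positive_group
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    if auto_orient:
        auc = max(auc, 1.0 - auc)
    return RocResult(auc=float(auc), positive_group=positive_group,
                     n_pos=n_pos, n_neg=n_neg)


def bonferroni_adjust(p_list, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m*p) elementwise; m defaults to len(p)."""
    p_arr = list(p_list)
    if m is None:
        m = len(p_arr)
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for p in p_arr:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p value {p} outside (0, 1]")
        out.append(min(1.0, m * p))
    return out
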