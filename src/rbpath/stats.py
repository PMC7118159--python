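"""Statistical kernels shared by every analytic stage.

Thin, contract-enforcing wrappers over scipy / lifelines / scikit-learn:
Pearson correlation with the two-sided t-transform p-value, pooled-variance
Student t-test, odds-ratio + Fisher exact co-occurrence calls, upper-tail
hypergeometric overlap, Kaplan-Meier product-limit curves with the log-rank
test, and seeded multi-restart k-means.  Each kernel is checked against a
brute-force oracle in the test suite.

No multiple-testing correction is applied by default — downstream filters
operate on raw p < 0.05; Benjamini-Hochberg adjusted columns are offered via
:func:`bh_adjust` for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "ContingencyTable2x2",
    "CorrelationResult",
    "OddsRatioResult",
    "SurvivalComparison",
    "pearson_correlation",
    "two_sample_t_test",
    "odds_ratio_test",
    "hypergeometric_overlap",
    "km_logrank",
    "kmeans_partition",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a=both, b=only first, c=only second, d=neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 table cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("2x2 table must have positive total")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float  # NaN when undefined (zero-margin table)
    log_or: float
    p: float
    call: str  # co_occurring | mutually_exclusive | NA


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False  # zero pooled variance


@dataclass
class SurvivalComparison:
    curves: dict  # group -> DataFrame(time, at_risk, survival)
    chi2: float
    p: float
    df: int
    unreliable: bool = False  # a group contributed zero events
    group_sizes: dict = field(default_factory=dict)


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided p from the t transform.

    Requires n >= 3 and non-constant vectors; p is the two-sided tail of
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def two_sample_t_test(a, b, welch: bool = False) -> TTestResult:
    """Two-sided Student t-test, pooled variance by default (Welch by flag).

    Zero pooled variance is degenerate: t=0, p=1 when the means agree,
    p -> 0 (flagged) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=np.inf if np.mean(a) > np.mean(b) else -np.inf,
                           p=0.0, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(t), p=float(p))


def odds_ratio_test(
    table: ContingencyTable2x2, haldane_anscombe: bool = False
) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with two-sided Fisher exact p.

    No continuity correction by default: with a zero margin the OR is
    undefined and reported NA while the Fisher p is still computed, matching
    the convention of printing "NA" next to a p-value for such cohorts.
    ``haldane_anscombe`` adds +0.5 to every cell (for the OR only) when any
    cell is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    if haldane_anscombe and (0 in (a, b, c, d)):
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        or_ = (a2 * d2) / (b2 * c2)
    else:
        # zero margin (entire row or column empty) leaves the OR undefined
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return OddsRatioResult(np.nan, np.nan, float(p), "NA")
        if b * c == 0 and a * d == 0:
            return OddsRatioResult(np.nan, np.nan, float(p), "NA")
        if b * c == 0:
            or_ = np.inf
        else:
            or_ = (a * d) / (b * c)
    log_or = float(np.log(or_)) if or_ > 0 else -np.inf
    if or_ > 1:
        call = "co_occurring"
    elif or_ < 1:
        call = "mutually_exclusive"
    else:
        call = "NA"
    return OddsRatioResult(float(or_), log_or, float(p), call)


def hypergeometric_overlap(N: int, nA: int, nB: int, k: int) -> float:
    """Upper-tail P(X >= k) for the overlap of two sets drawn from N genes."""
    if not (0 <= nA <= N and 0 <= nB <= N):
        raise ValueError("set sizes must lie within the universe")
    if k > min(nA, nB) or k < 0:
        raise ValueError(f"impossible overlap k={k} for sets of {nA} and {nB}")
    return float(sps.hypergeom.sf(k - 1, N, nA, nB))


def km_logrank(times, events, group_labels) -> SurvivalComparison:
    """Product-limit survival curves per group plus the log-rank test.

    k-group chi-square on k-1 degrees of freedom; a group with zero events
    still gets a curve but flags the comparison unreliable.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    if times.size != events.size or times.size != labels.size:
        raise ValueError("times, events and group_labels must align")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")

    curves: dict = {}
    sizes: dict = {}
    zero_event = False
    for g in groups:
        m = labels == g
        sizes[str(g)] = int(m.sum())
        if events[m].sum() == 0:
            zero_event = True
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        ev = kmf.event_table
        curves[str(g)] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            }
        )
    res = multivariate_logrank_test(times, labels, events)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    return SurvivalComparison(
        curves=curves,
        chi2=chi2,
        p=p,
        df=len(groups) - 1,
        unreliable=zero_event,
        group_sizes=sizes,
    )


def kmeans_partition(matrix, k: int, seed: int, n_restarts: int = 25):
    """K-means with ``n_restarts`` seeded restarts, best within-cluster SS kept.

    Labels are canonicalized by lexicographic centroid order so a fixed seed
    yields identical labels regardless of scikit-learn's internal ordering.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if k <= 0 or k > X.shape[0]:
        raise ValueError(f"k={k} invalid for {X.shape[0]} rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    order = np.lexsort(km.cluster_centers_.T[::-1])  # sort centroids row-wise
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw]
    centroids = km.cluster_centers_[order]
    return labels, centroids


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw p)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = sps.false_discovery_control(p[ok], method="bh")
    return out
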