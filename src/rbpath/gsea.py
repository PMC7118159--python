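"""Signature-correlation mining with bootstrap cutoffs and pre-ranked GSEA.

For each cohort, every gene's expression is correlated (Pearson) with the
per-sample signature score.  A bootstrap over genes — resampling the
vector of correlation coefficients 10,000 times with replacement and
pooling the resampled values — yields empirical 95% cutoffs; genes beyond
a cutoff with p < 0.05 are called positively / negatively correlated.
Selected genes are weighted W = CC * (-log10 p) and fed to a weighted
Kolmogorov-Smirnov pre-ranked GSEA (gene-label permutations), and the
per-cohort correlation profiles are clustered into gene programs
(Ward hierarchical by default, k-means by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import ExpressionMatrix, GeneSetCollection
from .stats import kmeans_partition, pearson_correlation

__all__ = [
    "BootstrapCutoffs",
    "GseaResult",
    "genewise_correlation",
    "bootstrap_cutoffs",
    "apply_cutoffs",
    "gsea_weights",
    "preranked_gsea",
    "cluster_correlation_matrix",
]

P_FLOOR = 1e-300  # avoids infinite weights when a correlation p underflows


@dataclass(frozen=True)
class BootstrapCutoffs:
    lower: float
    upper: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower cutoff exceeds upper cutoff")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    n_members: int
    leading_edge: list


def genewise_correlation(expr: ExpressionMatrix, scores: pd.Series) -> pd.DataFrame:
    """Pearson r and p of every gene's expression vs the signature score.

    Constant genes are excluded with a notice column rather than an error.
    Returns a DataFrame indexed by gene with columns CC, p_val.
    """
    shared = [s for s in expr.sample_ids if s in scores.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 scored samples")
    score_vec = scores.loc[shared].to_numpy(dtype=float)
    X = expr.values[shared]
    rows = []
    for gene in X.index:
        v = X.loc[gene].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            continue  # constant gene: correlation undefined
        res = pearson_correlation(v, score_vec)
        rows.append((gene, res.r, res.p))
    return pd.DataFrame(rows, columns=["gene", "CC", "p_val"]).set_index("gene")


def bootstrap_cutoffs(
    profile: pd.DataFrame,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    per_resample_means: bool = False,
) -> BootstrapCutoffs:
    """Empirical confidence cutoffs from resampling gene correlations.

    The gene-level CC vector is resampled with replacement ``n_boot`` times
    (resample size = number of genes) and all resampled values are pooled;
    the cutoffs are the (1-level)/2 and (1+level)/2 quantiles of the pooled
    distribution.  The alternative reading — quantiles of the per-resample
    means, i.e. a bootstrap CI of the mean correlation — is available via
    ``per_resample_means``.

    Seeded generator contract (relied on by the oracle tests):
    ``rng = numpy.random.default_rng(seed)`` then a single
    ``rng.integers(0, n_genes, size=(n_boot, n_genes))`` index draw.
    """
    cc = profile["CC"].to_numpy(dtype=float)
    n = cc.size
    if n < 10:
        raise ValueError(f"need >= 10 genes with defined CC, got {n}")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; cutoffs will be noisy")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    resampled = cc[idx]
    pooled = resampled.mean(axis=1) if per_resample_means else resampled.ravel()
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(pooled, [alpha, 1.0 - alpha])
    return BootstrapCutoffs(float(lower), float(upper), n_boot, seed)


def apply_cutoffs(
    profile: pd.DataFrame, cutoffs: BootstrapCutoffs, p_max: float = 0.05
) -> pd.DataFrame:
    """Call each gene positive / negative / none against the cutoffs.

    Selection requires the correlation to lie strictly beyond a cutoff AND
    its p-value to be below ``p_max``.
    """
    out = profile.copy()
    out["selected"] = "none"
    sig = out["p_val"] < p_max
    out.loc[sig & (out["CC"] > cutoffs.upper), "selected"] = "positive"
    out.loc[sig & (out["CC"] < cutoffs.lower), "selected"] = "negative"
    return out


def gsea_weights(profile: pd.DataFrame, selected_only: bool = True) -> pd.DataFrame:
    """Rank genes by W = CC * (-log10 p), descending.

    Input is a correlation profile with columns CC, p_val (and ``selected``
    when ``selected_only``); p-values of 0 are floored at 1e-300 and
    flagged.  Ties in W are broken lexicographically by gene id, so the
    ordering is invariant to input order.
    """
    sub = profile
    if selected_only:
        if "selected" not in profile.columns:
            raise ValueError("profile has no 'selected' column; run apply_cutoffs")
        sub = profile[profile["selected"] != "none"]
    p = sub["p_val"].to_numpy(dtype=float)
    floored = p <= 0
    p = np.where(floored, P_FLOOR, p)
    out = pd.DataFrame(
        {
            "CC": sub["CC"].to_numpy(dtype=float),
            "p_val": sub["p_val"].to_numpy(dtype=float),
            "W": sub["CC"].to_numpy(dtype=float) * (-np.log10(p)),
            "p_floored": floored,
        },
        index=sub.index.copy(),
    )
    # two-key sort: W descending, gene id ascending on ties
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["W"].to_numpy()))]
    return out


def running_sum_es(weights: np.ndarray, in_set: np.ndarray) -> tuple[float, int]:
    """Weighted KS enrichment score over a ranked list.

    ``weights`` are the ranking weights in list order; ``in_set`` marks set
    membership.  Hits advance by |w| / sum(|w| over hits), misses retreat
    by 1/(N - Nh); the ES is the running-sum value of largest magnitude.
    Returns (ES, index of the extremum).
    """
    n = weights.size
    nh = int(in_set.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper non-empty subset of the ranked list")
    absw = np.abs(weights)
    hit_total = absw[in_set].sum()
    if hit_total == 0:
        hit_step = np.where(in_set, 1.0 / nh, 0.0)  # all-zero weights: unweighted steps
    else:
        hit_step = np.where(in_set, absw / hit_total, 0.0)
    miss_step = np.where(in_set, 0.0, 1.0 / (n - nh))
    running = np.cumsum(hit_step - miss_step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_gsea(
    ranked: pd.DataFrame,
    sets: GeneSetCollection | dict,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 2,
) -> list[GseaResult]:
    """Weighted pre-ranked GSEA with gene-label permutation p-values.

    ``ranked`` is the gsea_weights output (index gene, column W, already
    sorted).  For each set, the ES is the weighted running-sum extremum;
    the null re-draws the set's positions uniformly among the ranked genes
    (phenotypes cannot be permuted in pre-ranked mode).  NES divides the ES
    by the mean |permutation ES| of matching sign; p is the fraction of
    same-sign permutation scores at least as extreme, floored at
    1/(n_perm+1).  Sets with fewer than ``min_size`` present members, or
    spanning the whole list, are skipped.
    """
    if len(ranked) < 10:
        raise ValueError("ranked list must have >= 10 genes")
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    genes = ranked.index.to_numpy()
    weights = ranked["W"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    results: list[GseaResult] = []
    for name, members in items:
        idx = sorted(pos[m] for m in set(members) if m in pos)
        nh = len(idx)
        if nh < min_size or nh == len(genes):
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[idx] = True
        es, peak = running_sum_es(weights, in_set)
        if es >= 0:
            leading = [genes[i] for i in idx if i <= peak]
        else:
            leading = [genes[i] for i in idx if i >= peak]
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pidx = rng.choice(len(genes), size=nh, replace=False)
            mask = np.zeros(len(genes), dtype=bool)
            mask[pidx] = True
            perm_es[b], _ = running_sum_es(weights, mask)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same_sign.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = float("nan")
        else:
            p = max(
                float((np.abs(same_sign) >= abs(es)).sum()) / same_sign.size,
                1.0 / (n_perm + 1),
            )
            nes = es / float(np.abs(same_sign).mean())
        results.append(GseaResult(
            set_name=name, es=es, nes=float(nes), p=float(p),
            n_members=nh, leading_edge=leading,
        ))
    return results


def cluster_correlation_matrix(
    cc_matrix: pd.DataFrame,
    k: int = 5,
    method: str = "ward",
    seed: int = 0,
):
    """Cluster genes by their per-cohort correlation profiles.

    ``cc_matrix`` is genes x cohorts of correlation coefficients; missing
    entries (gene not selected / measured in a cohort) are imputed as 0
    with the mask recorded.  Default is Ward-linkage hierarchical
    clustering cut at ``k``; ``method='kmeans'`` switches to the seeded
    k-means partition.  Returns (labels Series, imputation mask DataFrame,
    degenerate flag for identical rows).
    """
    if cc_matrix.shape[0] < k:
        raise ValueError(f"k={k} exceeds {cc_matrix.shape[0]} genes")
    mask = cc_matrix.isna()
    X = cc_matrix.fillna(0.0).to_numpy(dtype=float)
    degenerate = bool(np.all(X == X[0]))
    if method == "ward":
        if degenerate:
            labels = np.ones(X.shape[0], dtype=int)
        else:
            Z = linkage(X, method="ward", metric="euclidean")
            labels = fcluster(Z, t=k, criterion="maxclust")
        labels = labels - labels.min()
    elif method == "kmeans":
        labels, _ = kmeans_partition(X, k=k, seed=seed)
    else:
        raise ValueError("method must be 'ward' or 'kmeans'")
    return (
        pd.Series(labels, index=cc_matrix.index, name="cluster"),
        mask,
        degenerate,
    )
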