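"""Derivation and application of the CDK4/6-RB integrated signature.

The signature is derived in three steps from an isogenic perturbation
experiment (parental vs RB1-null cells, vehicle vs CDK4/6-inhibitor):

1. genes repressed by drug in the parental line (log2FC <= -1, p < 0.05 on
   log2(CPM+1), plain two-sample Student t-test on the replicates);
2. an RB-dependency filter removing genes that are also repressed in the
   identically treated RB1-null line (their repression does not require RB);
3. a correlation prune on a large clinical cohort: each surviving gene's
   maximum Pearson correlation to any other surviving gene is computed and
   genes whose maximum falls strictly below the mean of those maxima are
   dropped — keeping only the co-regulated clinical module.

Tumors are then scored as the mean of per-gene z-scores across the cohort
and stratified into lowest 25% / middle 50% / highest 25% for
Kaplan-Meier comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, ExpressionMatrix
from .stats import bh_adjust, km_logrank, two_sample_t_test, SurvivalComparison

__all__ = [
    "SignatureModel",
    "ScoreTable",
    "cpm_normalize",
    "differential_expression",
    "repressed_genes",
    "rb_dependency_filter",
    "correlation_prune",
    "score_samples",
    "stratify_and_compare",
]


@dataclass
class SignatureModel:
    """Ordered signature gene list plus derivation provenance."""

    genes: list[str]
    seed_genes: list[str]
    pruned_genes: list[str]
    max_correlation: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature is empty")
        if set(self.genes) | set(self.pruned_genes) != set(self.seed_genes) or (
            set(self.genes) & set(self.pruned_genes)
        ):
            raise ValueError("final list must equal seed genes minus pruned genes")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "genes": self.genes,
            "seed_genes": self.seed_genes,
            "pruned_genes": self.pruned_genes,
            "max_correlation": self.max_correlation,
            "params": self.params,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class ScoreTable:
    """Per-sample signature score (mean of gene z-scores) and stratum."""

    scores: pd.Series            # index sample
    strata: pd.Series | None     # low25 | mid50 | high25 (set by stratify)
    used_genes: list[str]
    missing_genes: list[str]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / column library size x 1e6."""
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"zero library size in column {bad!r}")
    return counts / lib * 1e6


def differential_expression(
    cpm: pd.DataFrame, treated_cols, control_cols, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene log2 fold change (treated vs control) and Student t p-value.

    Both the fold change and the test operate on log2(CPM + pseudocount).
    """
    treated_cols, control_cols = list(treated_cols), list(control_cols)
    if len(treated_cols) < 2 or len(control_cols) < 2:
        raise ValueError("need >= 2 columns per group")
    logged = np.log2(cpm + pseudocount)
    t_arr = logged[treated_cols].to_numpy()
    c_arr = logged[control_cols].to_numpy()
    rows = []
    for i, gene in enumerate(cpm.index):
        res = two_sample_t_test(t_arr[i], c_arr[i])
        rows.append((
            gene,
            float(t_arr[i].mean() - c_arr[i].mean()),
            res.p,
            float(t_arr[i].mean()),
            float(c_arr[i].mean()),
        ))
    out = pd.DataFrame(
        rows, columns=["gene", "log2_fc", "p", "mean_treated", "mean_control"]
    ).set_index("gene")
    out["n_treated"] = len(treated_cols)
    out["n_control"] = len(control_cols)
    out["p_bh"] = bh_adjust(out["p"])
    return out


def repressed_genes(
    cpm: pd.DataFrame,
    treated_cols,
    control_cols,
    lfc_max: float = -1.0,
    p_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genes downregulated under treatment: log2FC <= lfc_max and p < p_max."""
    de = differential_expression(cpm, treated_cols, control_cols, pseudocount)
    return de[(de["log2_fc"] <= lfc_max) & (de["p"] < p_max)]


def rb_dependency_filter(
    parental_hits,
    ko_de: pd.DataFrame,
    lfc_max: float = -1.0,
    p_max: float = 0.05,
) -> list[str]:
    """Keep parental-repressed genes that are NOT repressed in the knockout.

    ``ko_de`` is the full differential-expression table of the RB1-null line
    under identical treatment and thresholds.  A gene missing from the
    knockout data is retained with a warning (its dependency cannot be
    disproved).
    """
    parental_hits = list(parental_hits)
    seed = []
    for g in parental_hits:
        if g not in ko_de.index:
            warnings.warn(f"gene {g!r} absent from knockout data; retained")
            seed.append(g)
            continue
        row = ko_de.loc[g]
        repressed_in_ko = row["log2_fc"] <= lfc_max and row["p"] < p_max
        if not repressed_in_ko:
            seed.append(g)
    return seed


def correlation_prune(
    seed_genes,
    clinical_expr: ExpressionMatrix,
    absolute: bool = False,
) -> SignatureModel:
    """Drop seed genes poorly correlated with the rest of the seed in tumors.

    For every seed gene present in the clinical matrix, the maximum Pearson
    correlation to any other seed gene is computed (signed by default; the
    co-repressed module is expected to correlate positively — set
    ``absolute`` for |r|).  Genes with a maximum strictly below the mean of
    the maxima are pruned; genes exactly at the mean survive.
    """
    seed_genes = list(dict.fromkeys(seed_genes))
    present = [g for g in seed_genes if g in clinical_expr.values.index]
    dropped_missing = [g for g in seed_genes if g not in clinical_expr.values.index]
    if dropped_missing:
        warnings.warn(
            f"{len(dropped_missing)} seed genes absent from the clinical matrix; dropped"
        )
    if len(present) < 2:
        raise ValueError("need >= 2 seed genes present in the clinical matrix")

    X = clinical_expr.values.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        const = [g for g, s in zip(present, sd) if s == 0]
        warnings.warn(f"constant expression for {const}; dropped before pruning")
        present = [g for g in present if g not in set(const)]
        X = clinical_expr.values.loc[present].to_numpy(dtype=float)
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, -np.inf)
    if absolute:
        corr = np.abs(corr)
    max_corr = corr.max(axis=1)
    threshold = float(max_corr.mean())
    keep = max_corr >= threshold  # strict less-than is pruned
    final = [g for g, k in zip(present, keep) if k]
    pruned = [g for g, k in zip(present, keep) if not k] + dropped_missing
    return SignatureModel(
        genes=final,
        seed_genes=list(seed_genes),
        pruned_genes=pruned,
        max_correlation={g: float(m) for g, m in zip(present, max_corr)},
        params={
            "absolute": absolute,
            "threshold": threshold,
            "n_clinical_samples": len(clinical_expr.sample_ids),
        },
    )


def score_samples(
    expr: ExpressionMatrix,
    signature: SignatureModel | list,
    min_coverage: float = 0.5,
) -> ScoreTable:
    """Mean per-gene z-score of the signature genes for every sample.

    Each signature gene is z-scored across the cohort; a sample's score is
    the mean over available genes.  Fails if fewer than ``min_coverage`` of
    the signature genes are present.
    """
    genes = signature.genes if isinstance(signature, SignatureModel) else list(signature)
    present = [g for g in genes if g in expr.values.index]
    missing = [g for g in genes if g not in expr.values.index]
    if len(present) < min_coverage * len(genes):
        raise ValueError(
            f"only {len(present)}/{len(genes)} signature genes present; "
            f"missing: {missing}"
        )
    X = expr.values.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1)
    usable = sd > 0
    if not usable.all():
        const = [g for g, u in zip(present, usable) if not u]
        warnings.warn(f"constant genes excluded from scoring: {const}")
        missing = missing + const
        present = [g for g, u in zip(present, usable) if u]
        X = X[usable]
        sd = sd[usable]
    z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = pd.Series(z.mean(axis=0), index=expr.values.columns, name="score")
    return ScoreTable(scores=scores, strata=None, used_genes=present, missing_genes=missing)


def stratify(scores: pd.Series, low_frac: float = 0.25, high_frac: float = 0.25) -> pd.Series:
    """Assign low25 / mid50 / high25 strata by score rank.

    Samples are ranked with a stable sort; the lowest floor(n*low_frac) form
    the low stratum and the highest floor(n*high_frac) the high stratum.
    Ties straddling a boundary are moved to the middle stratum, so the
    strata are deterministic; fully tied scores empty both tails, which is
    an error naming the collision.
    """
    n = scores.size
    if n < 8:
        raise ValueError("need >= 8 samples to stratify")
    order = np.argsort(scores.to_numpy(), kind="stable")
    n_low = int(np.floor(n * low_frac))
    n_high = int(np.floor(n * high_frac))
    vals = scores.to_numpy()
    labels = np.array(["mid50"] * n, dtype=object)
    low_idx = order[:n_low]
    high_idx = order[n - n_high:]
    # boundary ties go to the middle stratum
    low_cut = vals[order[n_low - 1]]
    if n_low < n and vals[order[n_low]] == low_cut:
        low_idx = low_idx[vals[low_idx] < low_cut]
    high_cut = vals[order[n - n_high]]
    if n_high < n and vals[order[n - n_high - 1]] == high_cut:
        high_idx = high_idx[vals[high_idx] > high_cut]
    labels[low_idx] = "low25"
    labels[high_idx] = "high25"
    if len(low_idx) == 0 or len(high_idx) == 0:
        raise ValueError(
            f"stratification collapsed: tied scores at the "
            f"{'25th' if len(low_idx) == 0 else '75th'} percentile "
            f"(value {low_cut if len(low_idx) == 0 else high_cut})"
        )
    return pd.Series(labels, index=scores.index, name="stratum")


def stratify_and_compare(
    score_table: ScoreTable,
    clinical: ClinicalTable,
    endpoint: str = "dfs",
    subtype_groups: tuple[str, str] | None = None,
) -> dict:
    """Quantile-stratify scores and compare survival across strata.

    Returns the strata, the three-group Kaplan-Meier log-rank comparison on
    the requested endpoint, and (optionally) a two-group Student t-test of
    scores between two clinical subtypes.
    """
    strata = stratify(score_table.scores)
    score_table.strata = strata
    surv = clinical.endpoint(endpoint)
    shared = [s for s in strata.index if s in surv.index]
    if len(shared) < 8:
        raise ValueError(f"only {len(shared)} samples with {endpoint} data")
    comparison: SurvivalComparison = km_logrank(
        surv.loc[shared, "time"].to_numpy(),
        surv.loc[shared, "event"].to_numpy(dtype=int),
        strata.loc[shared].to_numpy(),
    )
    out = {"strata": strata, "survival": comparison}
    if subtype_groups is not None:
        g1, g2 = subtype_groups
        sub = clinical.rows["subtype"]
        v1 = score_table.scores[sub.reindex(score_table.scores.index) == g1]
        v2 = score_table.scores[sub.reindex(score_table.scores.index) == g2]
        if len(v1) >= 2 and len(v2) >= 2:
            res = two_sample_t_test(v1.to_numpy(), v2.to_numpy())
            out["subtype_test"] = {
                "groups": (g1, g2), "n": (len(v1), len(v2)),
                "mean_diff": float(v1.mean() - v2.mean()),
                "t": res.t, "p": res.p,
            }
    return out
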