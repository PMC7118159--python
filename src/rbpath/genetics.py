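"""Core-pathway genetics: alteration calls, co-occurrence, cohort clustering.

Reproduces the oncoprint-style analysis of the RB pathway: per-gene
categorical alteration calls from discrete copy number plus mutations,
per-cohort alteration frequencies, pairwise co-occurrence / mutual
exclusivity by odds ratio with Fisher exact p, k-means clustering of
cohorts by their four-gene alteration percentages, and the CDKN2A-RB1
expression correlation.

For exclusivity testing "altered" means amplification, deep deletion, or
non-silent mutation; heterozygous (single-copy) loss is tracked as its own
axis — it behaves differently (it co-occurs with CDK4/6-deregulating
events rather than excluding them) — and can be folded into "altered" via
``include_het``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CohortBundle, ExpressionMatrix
from .stats import (
    ContingencyTable2x2,
    CorrelationResult,
    kmeans_partition,
    odds_ratio_test,
    pearson_correlation,
    bh_adjust,
)

__all__ = [
    "AlterationMatrix",
    "call_alterations",
    "pairwise_cooccurrence",
    "cluster_cohorts",
    "expression_pair_correlation",
]

EVENT_CLASSES = ("amplification", "deep_deletion", "het_loss", "mutation")
DEFAULT_ALTERED = frozenset({"amplification", "deep_deletion", "mutation"})


@dataclass
class AlterationMatrix:
    """Categorical calls plus per-class boolean masks for one cohort."""

    calls: pd.DataFrame            # genes x samples in {amplification, deep_deletion,
    #                                het_loss, mutation, multiple, none}
    masks: dict                    # class -> genes x samples boolean DataFrame
    frequencies: pd.DataFrame      # per gene: fraction per class + fraction altered
    cohort_label: str = ""

    def altered(self, classes=DEFAULT_ALTERED) -> pd.DataFrame:
        """Boolean genes x samples: any event of the given classes."""
        acc = None
        for cls in classes:
            m = self.masks[cls]
            acc = m if acc is None else (acc | m)
        return acc

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


def call_alterations(bundle: CohortBundle, gene_list) -> AlterationMatrix:
    """Classify each gene x sample into the oncoprint event classes.

    amplification <=> CNA=+2, deep_deletion <=> CNA=-2, het_loss <=> CNA=-1,
    mutation <=> any non-silent mutation row; "multiple" when >=2 distinct
    classes hit the same gene in the same sample.  A gene absent from both
    the CNA and mutation tables yields an all-none row with a warning.
    """
    samples = bundle.sample_ids
    gene_list = list(gene_list)
    cna = bundle.cna.values
    mut = bundle.mutations.rows

    masks = {
        cls: pd.DataFrame(False, index=gene_list, columns=samples)
        for cls in EVENT_CLASSES
    }
    for g in gene_list:
        in_cna = g in cna.index
        has_mut = (mut["gene_id"] == g).any()
        if not in_cna and not has_mut:
            warnings.warn(f"gene {g!r} absent from CNA and mutation tables; all-none row")
            continue
        if in_cna:
            row = cna.loc[g]
            masks["amplification"].loc[g] = (row == 2).to_numpy()
            masks["deep_deletion"].loc[g] = (row == -2).to_numpy()
            masks["het_loss"].loc[g] = (row == -1).to_numpy()
        if has_mut:
            mutated = set(mut.loc[mut["gene_id"] == g, "sample_id"])
            masks["mutation"].loc[g] = [s in mutated for s in samples]

    n_classes = sum(m.to_numpy().astype(int) for m in masks.values())
    calls = pd.DataFrame("none", index=gene_list, columns=samples)
    for cls in EVENT_CLASSES:
        calls = calls.mask(masks[cls] & (n_classes == 1), cls)
    calls = calls.mask(pd.DataFrame(n_classes > 1, index=gene_list, columns=samples),
                       "multiple")

    n = len(samples)
    freq = pd.DataFrame(
        {cls: masks[cls].sum(axis=1) / n for cls in EVENT_CLASSES}
    )
    any_altered = None
    for cls in DEFAULT_ALTERED:
        m = masks[cls]
        any_altered = m if any_altered is None else (any_altered | m)
    freq["altered"] = any_altered.sum(axis=1) / n
    return AlterationMatrix(
        calls=calls, masks=masks, frequencies=freq,
        cohort_label=bundle.cohort_label,
    )


def pairwise_cooccurrence(
    altmats,
    genes,
    include_het: bool = False,
    pooled: bool = False,
) -> pd.DataFrame:
    """Odds-ratio co-occurrence grid over all gene pairs.

    ``altmats`` is a single :class:`AlterationMatrix` or a list of them (one
    per cohort).  With ``pooled=True`` samples are concatenated across
    cohorts into one pan-cancer test per pair.  Returns a long-format table
    with the 2x2 counts, odds ratio, log OR, Fisher p (plus BH-adjusted
    column) and the co-occurring / mutually-exclusive call; pairs where a
    gene is never altered carry an NA odds ratio with the p still reported.
    """
    if isinstance(altmats, AlterationMatrix):
        altmats = [altmats]
    classes = DEFAULT_ALTERED | ({"het_loss"} if include_het else set())
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for pairwise testing")

    per_cohort = {am.cohort_label or f"cohort{i}": am.altered(classes).loc[genes]
                  for i, am in enumerate(altmats)}
    if pooled:
        per_cohort = {"pan_cancer": pd.concat(per_cohort.values(), axis=1)}

    rows = []
    for label, altered in per_cohort.items():
        arr = altered.to_numpy(dtype=bool)
        for i, gi in enumerate(genes):
            for j in range(i + 1, len(genes)):
                gj = genes[j]
                a = int((arr[i] & arr[j]).sum())
                b = int((arr[i] & ~arr[j]).sum())
                c = int((~arr[i] & arr[j]).sum())
                d = int((~arr[i] & ~arr[j]).sum())
                res = odds_ratio_test(ContingencyTable2x2(a, b, c, d))
                rows.append((label, gi, gj, a, b, c, d,
                             res.odds_ratio, res.log_or, res.p, res.call))
    out = pd.DataFrame(
        rows,
        columns=["cohort", "gene_a", "gene_b", "a", "b", "c", "d",
                 "odds_ratio", "log_or", "p", "call"],
    )
    out["p_bh"] = bh_adjust(out["p"])
    return out


def cluster_cohorts(freq_table: pd.DataFrame, k: int = 5, seed: int = 0):
    """K-means over cohorts' alteration percentages (rows=cohorts).

    Returns (labels Series indexed by cohort, centroids, degenerate flag);
    the flag is set when all cohorts share one profile.
    """
    if freq_table.shape[0] < k:
        raise ValueError(f"need >= {k} cohorts for k={k}, got {freq_table.shape[0]}")
    X = freq_table.to_numpy(dtype=float)
    degenerate = bool(np.all(X == X[0]))
    labels, centroids = kmeans_partition(X, k=k, seed=seed)
    return pd.Series(labels, index=freq_table.index, name="cluster"), centroids, degenerate


def expression_pair_correlation(
    expr: ExpressionMatrix, gene_a: str = "CDKN2A", gene_b: str = "RB1"
) -> CorrelationResult:
    """Pearson correlation of two genes' expression across a cohort."""
    for g in (gene_a, gene_b):
        if g not in expr.values.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    return pearson_correlation(
        expr.values.loc[gene_a].to_numpy(), expr.values.loc[gene_b].to_numpy()
    )
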