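"""Chromosome-arm dosage analysis: loss-frequency profiles along 13q,
expression by gene dosage, and survival stratified by dosage.

Dosage classes come straight from the discrete copy-number codes (no
re-segmentation): diploid=0, heterozygous loss=-1, deep deletion=-2.
Frequency denominators are the full cohort (all samples, not just tumors
with a 13q event).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CohortBundle
from .stats import SurvivalComparison, km_logrank, two_sample_t_test

__all__ = ["ArmProfile", "arm_profile", "expression_by_dosage", "survival_by_dosage"]

DOSAGE_LABELS = {0: "diploid", -1: "het_loss", -2: "deep_deletion"}


@dataclass
class ArmProfile:
    """Per-gene loss frequencies ordered by chromosomal position."""

    table: pd.DataFrame  # index gene (position order); start, het_loss_freq,
    #                      deep_deletion_freq
    chrom: str
    arm: str
    markers: dict  # marker gene -> start coordinate (e.g. RB1, BRCA2)


def arm_profile(bundle: CohortBundle, chrom: str = "13", arm: str = "q",
                markers=("RB1", "BRCA2")) -> ArmProfile:
    """Frequencies of het loss (-1) and deep deletion (-2) per gene along the arm."""
    ann = bundle.annotation.on_arm(chrom, arm)
    genes = [g for g in ann.index if g in bundle.cna.values.index]
    if not genes:
        raise ValueError(f"no genes annotated on {chrom}{arm} present in the CNA table")
    n = len(bundle.sample_ids)
    sub = bundle.cna.values.loc[genes]
    table = pd.DataFrame(
        {
            "start": ann.loc[genes, "start"],
            "het_loss_freq": (sub == -1).sum(axis=1) / n,
            "deep_deletion_freq": (sub == -2).sum(axis=1) / n,
        },
        index=pd.Index(genes, name="gene"),
    )
    marks = {m: int(ann.loc[m, "start"]) for m in markers if m in ann.index}
    return ArmProfile(table=table, chrom=str(chrom), arm=arm, markers=marks)


def _dosage_groups(bundle: CohortBundle, gene: str) -> dict[str, list[str]]:
    if gene not in bundle.cna.values.index:
        raise KeyError(f"gene {gene!r} not in CNA table")
    row = bundle.cna.values.loc[gene]
    return {
        label: list(row.index[row == code]) for code, label in DOSAGE_LABELS.items()
    }


def expression_by_dosage(bundle: CohortBundle, gene: str = "RB1") -> dict:
    """Per-dosage expression summaries plus pairwise Student t-tests.

    Compares diploid vs heterozygous loss and diploid vs deep deletion;
    a class with fewer than 2 samples is skipped with a notice.  Summaries
    are the box-plot statistics (median, quartiles, min/max) per class.
    """
    if gene not in bundle.expression.values.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    groups = _dosage_groups(bundle, gene)
    exp = bundle.expression.values.loc[gene]

    summaries = {}
    vectors = {}
    for label, samples in groups.items():
        v = exp.loc[samples].to_numpy(dtype=float)
        vectors[label] = v
        if v.size:
            summaries[label] = {
                "n": int(v.size),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "min": float(v.min()),
                "max": float(v.max()),
                "mean": float(v.mean()),
            }
    tests = {}
    skipped = []
    for contrast in ("het_loss", "deep_deletion"):
        if vectors["diploid"].size >= 2 and vectors[contrast].size >= 2:
            res = two_sample_t_test(vectors["diploid"], vectors[contrast])
            tests[f"diploid_vs_{contrast}"] = {
                "t": res.t, "p": res.p,
                "mean_diff": float(vectors["diploid"].mean() - vectors[contrast].mean()),
                "degenerate": res.degenerate,
            }
        else:
            skipped.append(f"diploid_vs_{contrast}")
    return {"gene": gene, "summaries": summaries, "tests": tests, "skipped": skipped}


def survival_by_dosage(bundle: CohortBundle, gene: str = "RB1",
                       endpoint: str = "dfs") -> SurvivalComparison:
    """Kaplan-Meier + log-rank: diploid vs heterozygous loss of ``gene``.

    Deep deletions are excluded from this comparison; the endpoint (dfs/os)
    must be stated explicitly.
    """
    groups = _dosage_groups(bundle, gene)
    surv = bundle.clinical.endpoint(endpoint)
    frames = []
    for label in ("diploid", "het_loss"):
        samples = [s for s in groups[label] if s in surv.index]
        if not samples:
            raise ValueError(f"dosage class {label!r} has no samples with {endpoint} data")
        sub = surv.loc[samples].copy()
        sub["group"] = label
        frames.append(sub)
    joined = pd.concat(frames)
    return km_logrank(
        joined["time"].to_numpy(),
        joined["event"].to_numpy(dtype=int),
        joined["group"].to_numpy(),
    )
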