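"""Differential expression by RB1 gene dosage across cohorts.

Per cohort, genes are tested diploid vs heterozygous-loss or diploid vs
deep-deletion (|log2FC| >= 1, p < 0.05, Student t on log2 expression);
cross-cohort recurrence filters keep genes significant in the same
direction in more than 33% (het) / 66% (deep) of eligible cohorts, where a
cohort is eligible if its deep-deletion frequency exceeds 5% (deep
contrast) or its het-loss frequency exceeds 10% (het contrast).  The
down-regulated survivors are classified cis/trans by 13q location, and
up-set / signature overlaps are tested hypergeometrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CohortBundle, GeneAnnotation
from .stats import bh_adjust, hypergeometric_overlap, two_sample_t_test

__all__ = [
    "RecurrentGeneSets",
    "dosage_de",
    "recurrence_filter",
    "cis_fraction",
    "overlap_tests",
]

CONTRASTS = {"diploid_vs_het": -1, "diploid_vs_deep": -2}
#: eligibility thresholds (strict >) for the cross-cohort recurrence step
ELIGIBILITY = {"diploid_vs_het": ("het_loss", 0.10), "diploid_vs_deep": ("deep_deletion", 0.05)}
DEFAULT_MIN_FRACTION = {"diploid_vs_het": 0.33, "diploid_vs_deep": 0.66}


@dataclass
class RecurrentGeneSets:
    """Recurrently dosage-responsive genes for one contrast."""

    contrast: str
    up: list[str]
    down: list[str]
    recurrence_fraction: pd.DataFrame  # per gene: up_fraction, down_fraction
    eligible_cohorts: list[str]
    min_fraction: float = 0.0


def dosage_de(
    bundle: CohortBundle,
    gene: str = "RB1",
    contrast: str = "diploid_vs_deep",
    lfc_abs_min: float = 1.0,
    p_max: float = 0.05,
) -> pd.DataFrame | None:
    """Genome-wide DE between diploid and reduced-dosage tumors.

    Returns the full per-gene table (log2_fc of the altered class relative
    to diploid, p, significance direction) or ``None`` when either class
    has fewer than 2 samples (the cohort is ineligible for this contrast).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(CONTRASTS)}")
    code = CONTRASTS[contrast]
    cna_row = bundle.cna.values.loc[gene]
    diploid = list(cna_row.index[cna_row == 0])
    altered = list(cna_row.index[cna_row == code])
    if len(diploid) < 2 or len(altered) < 2:
        return None
    expr = bundle.expression.values
    X_alt = expr[altered].to_numpy()
    X_dip = expr[diploid].to_numpy()
    rows = []
    for i, g in enumerate(expr.index):
        if np.var(X_alt[i]) == 0 and np.var(X_dip[i]) == 0:
            rows.append((g, float(X_alt[i].mean() - X_dip[i].mean()), 1.0))
            continue
        res = two_sample_t_test(X_alt[i], X_dip[i])
        rows.append((g, float(X_alt[i].mean() - X_dip[i].mean()), res.p))
    out = pd.DataFrame(rows, columns=["gene", "log2_fc", "p"]).set_index("gene")
    out["p_bh"] = bh_adjust(out["p"])
    sig = (out["p"] < p_max) & (out["log2_fc"].abs() >= lfc_abs_min)
    out["direction"] = "ns"
    out.loc[sig & (out["log2_fc"] > 0), "direction"] = "up"
    out.loc[sig & (out["log2_fc"] < 0), "direction"] = "down"
    return out


def cohort_eligible(bundle: CohortBundle, contrast: str, gene: str = "RB1") -> bool:
    """Strict frequency threshold: >5% deep deletion / >10% het loss of ``gene``."""
    code_name, threshold = ELIGIBILITY[contrast]
    code = {"het_loss": -1, "deep_deletion": -2}[code_name]
    row = bundle.cna.values.loc[gene]
    return float((row == code).mean()) > threshold


def recurrence_filter(
    de_tables: dict,
    contrast: str,
    min_fraction: float | None = None,
) -> RecurrentGeneSets:
    """Keep genes significant in the same direction in > min_fraction of cohorts.

    ``de_tables`` maps eligible cohort label -> dosage_de table (``None``
    entries — cohorts without both classes — are excluded from the
    denominator).  Directions are counted separately, so a discordant gene
    can fail both; thresholds are strict (>).
    """
    if min_fraction is None:
        min_fraction = DEFAULT_MIN_FRACTION[contrast]
    usable = {k: v for k, v in de_tables.items() if v is not None}
    if len(usable) < 2:
        raise ValueError(f"need >= 2 eligible cohorts, got {len(usable)}")
    denom = len(usable)
    all_genes = sorted(set().union(*(set(t.index) for t in usable.values())))
    up_counts = pd.Series(0, index=all_genes)
    down_counts = pd.Series(0, index=all_genes)
    for t in usable.values():
        up_counts = up_counts.add((t["direction"] == "up").reindex(all_genes, fill_value=False).astype(int), fill_value=0)
        down_counts = down_counts.add((t["direction"] == "down").reindex(all_genes, fill_value=False).astype(int), fill_value=0)
    frac = pd.DataFrame({
        "up_fraction": up_counts / denom,
        "down_fraction": down_counts / denom,
    })
    up = list(frac.index[frac["up_fraction"] > min_fraction])
    down = list(frac.index[frac["down_fraction"] > min_fraction])
    return RecurrentGeneSets(
        contrast=contrast, up=up, down=down, recurrence_fraction=frac,
        eligible_cohorts=sorted(usable), min_fraction=float(min_fraction),
    )


def cis_fraction(
    gene_set,
    annotation: GeneAnnotation,
    chrom: str = "13",
    arm: str = "q",
) -> tuple[float, pd.Series]:
    """Fraction of a gene set located on the given chromosome arm.

    Unannotated members count as trans with a warning; an empty set has no
    defined fraction and is an error.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("cis fraction undefined for an empty gene set")
    arm_genes = set(annotation.on_arm(chrom, arm).index)
    labels = {}
    for g in gene_set:
        if g not in annotation.rows.index:
            warnings.warn(f"gene {g!r} unannotated; counted as trans")
            labels[g] = "trans"
        else:
            labels[g] = "cis" if g in arm_genes else "trans"
    lab = pd.Series(labels, name="location")
    return float((lab == "cis").mean()), lab


def overlap_tests(sets: dict, universe) -> dict:
    """Pairwise hypergeometric overlap p-values plus Venn counts.

    ``sets`` maps name -> gene collection; every member must belong to the
    ``universe`` (genes measured in all analyzed cohorts).
    """
    universe = set(universe)
    clean = {name: set(s) for name, s in sets.items()}
    for name, s in clean.items():
        stray = sorted(s - universe)
        if stray:
            raise ValueError(f"set {name!r} has members outside the universe: {stray}")
    names = list(clean)
    N = len(universe)
    pairwise = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            k = len(clean[na] & clean[nb])
            pairwise[f"{na}|{nb}"] = {
                "overlap": k,
                "nA": len(clean[na]),
                "nB": len(clean[nb]),
                "p": hypergeometric_overlap(N, len(clean[na]), len(clean[nb]), k),
            }
    venn = {}
    if len(names) == 3:
        a, b, c = (clean[n] for n in names)
        venn = {
            "only_" + names[0]: len(a - b - c),
            "only_" + names[1]: len(b - a - c),
            "only_" + names[2]: len(c - a - b),
            names[0] + "&" + names[1]: len((a & b) - c),
            names[0] + "&" + names[2]: len((a & c) - b),
            names[1] + "&" + names[2]: len((b & c) - a),
            "all_three": len(a & b & c),
        }
    return {"universe_size": N, "pairwise": pairwise, "venn": venn}
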