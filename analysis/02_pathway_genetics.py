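"""Core-pathway genetics on the simulated study.

Loads the cohort files written by 01_simulate.py, calls alterations for
CCND1/CDK4/CDKN2A/RB1, reports per-cohort alteration frequencies, the
pairwise co-occurrence / mutual-exclusivity grid (per cohort and pooled),
a k-means grouping of cohorts by their alteration percentages, and the
CDKN2A-RB1 expression correlation per cohort.
"""

import argparse
from pathlib import Path

import pandas as pd

from rbpath import genetics
from rbpath.core_io import load_cohort_bundle, write_results
from rbpath.simulate import PATHWAY_GENES

GENES = list(PATHWAY_GENES)


def load_bundles(indir: Path):
    for d in sorted(p for p in indir.iterdir() if p.is_dir()):
        yield load_cohort_bundle(
            d / "expression.tsv", d / "cna.tsv", d / "mutations.tsv",
            d / "clinical.tsv", d / "annotation.tsv", cohort_label=d.name,
        )


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/genetics"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundles = list(load_bundles(args.indir))
    altmats = [genetics.call_alterations(b, GENES) for b in bundles]

    freq = pd.concat(
        {am.cohort_label: am.frequencies for am in altmats}, names=["cohort", "gene"]
    )
    write_results(freq, args.out / "alteration_frequencies.tsv")

    per = genetics.pairwise_cooccurrence(altmats, GENES)
    pooled = genetics.pairwise_cooccurrence(altmats, GENES, pooled=True)
    grid = pd.concat([per, pooled], ignore_index=True)
    write_results(grid.set_index("cohort"), args.out / "cooccurrence.tsv")
    print("pan-cancer pooled odds ratios:")
    for r in pooled.itertuples():
        print(f"  {r.gene_a:7s} x {r.gene_b:7s} OR={r.odds_ratio:8.3f} "
              f"p={r.p:10.3g} {r.call}")

    pct = freq["altered"].unstack("gene")[GENES] * 100
    k = 2 if len(bundles) < 5 else 5
    labels, _, degenerate = genetics.cluster_cohorts(pct, k=k, seed=args.seed)
    write_results(labels.to_frame(), args.out / "cohort_clusters.tsv")
    print(f"\ncohort clusters (k={k}{', degenerate' if degenerate else ''}):",
          dict(labels))

    rows = []
    for b in bundles:
        res = genetics.expression_pair_correlation(b.expression)
        rows.append((b.cohort_label, res.r, res.p, res.n))
        print(f"CDKN2A~RB1 expression in {b.cohort_label}: "
              f"r={res.r:+.3f} p={res.p:.3g}")
    write_results(
        pd.DataFrame(rows, columns=["cohort", "r", "p", "n"]).set_index("cohort"),
        args.out / "cdkn2a_rb1_correlation.tsv",
    )


if __name__ == "__main__":
    main()
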