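"""Signature-correlation mining, bootstrap cutoffs, and pre-ranked GSEA.

Per cohort: correlate every gene with the signature score, derive 95%
bootstrap cutoffs (10,000 gene resamples), select genes beyond the
cutoffs with p<0.05, rank them by W = CC * (-log10 p), and run weighted
pre-ranked GSEA against the planted gene sets.  Finally, cluster the
per-cohort correlation profiles of all selected genes into programs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rbpath import gsea, signature as sg
from rbpath.core_io import read_gmt, write_results
from rbpath.signature import SignatureModel

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "drivers02", Path(__file__).parent / "02_pathway_genetics.py")
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_bundles = _mod.load_bundles


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--signature", type=Path,
                    default=Path("results/signature/signature.json"))
    ap.add_argument("--gmt", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results/gsea"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-boot", type=int, default=10_000)
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--k", type=int, default=5)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    model = SignatureModel.from_json(args.signature)
    sets = read_gmt(args.gmt or args.indir / "gene_sets.gmt")

    cc_columns = {}
    selected_union = set()
    for b in load_bundles(args.indir):
        scores = sg.score_samples(b.expression, model).scores
        prof = gsea.genewise_correlation(b.expression, scores)
        cuts = gsea.bootstrap_cutoffs(prof, n_boot=args.n_boot, seed=args.seed)
        sel = gsea.apply_cutoffs(prof, cuts)
        write_results(sel, args.out / f"{b.cohort_label}_profile.tsv")
        (args.out / f"{b.cohort_label}_cutoffs.json").write_text(json.dumps(
            {"lower": cuts.lower, "upper": cuts.upper,
             "n_boot": cuts.n_boot, "seed": cuts.seed}, indent=1))
        chosen = sel[sel["selected"] != "none"]
        selected_union |= set(chosen.index)
        cc_columns[b.cohort_label] = prof["CC"]
        print(f"{b.cohort_label}: cutoffs [{cuts.lower:+.3f}, {cuts.upper:+.3f}], "
              f"{(sel['selected'] == 'positive').sum()} positive / "
              f"{(sel['selected'] == 'negative').sum()} negative genes")

        ranked = gsea.gsea_weights(sel)
        write_results(ranked, args.out / f"{b.cohort_label}_ranked.tsv")
        res = gsea.preranked_gsea(ranked, sets, n_perm=args.n_perm, seed=args.seed)
        out = pd.DataFrame(
            [(r.set_name, r.es, r.nes, r.p, r.n_members,
              ",".join(map(str, r.leading_edge))) for r in res],
            columns=["set", "ES", "NES", "p", "n_members", "leading_edge"],
        ).set_index("set")
        write_results(out, args.out / f"{b.cohort_label}_gsea.tsv")
        for r in res:
            print(f"   {r.set_name:8s} ES={r.es:+.3f} NES={r.nes:+.2f} p={r.p:.3g}")

    cc = pd.DataFrame(cc_columns).loc[sorted(selected_union)]
    k = min(args.k, len(cc))
    labels, mask, degenerate = gsea.cluster_correlation_matrix(cc, k=k, seed=args.seed)
    write_results(labels.to_frame(), args.out / "gene_clusters.tsv")
    print(f"clustered {len(cc)} selected genes into {labels.nunique()} programs"
          + (" (degenerate)" if degenerate else ""))


if __name__ == "__main__":
    main()
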