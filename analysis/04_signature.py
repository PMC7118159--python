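"""Derive the CDK4/6-RB integrated signature and stratify the cohorts.

From the isogenic counts: CPM-normalize, find drug-repressed genes in the
parental line (log2FC <= -1, p < 0.05), remove genes also repressed in the
RB1-null line (RB-dependency filter), then prune on the clinical
expression matrix by max-correlation.  Scores every tumor cohort, cuts
lowest-25% / middle-50% / highest-25% strata, and compares their survival.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rbpath import signature as sg
from rbpath.core_io import read_expression, write_results

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "drivers02", Path(__file__).parent / "02_pathway_genetics.py")
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_bundles = _mod.load_bundles


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/signature"))
    ap.add_argument("--endpoint", choices=["dfs", "os"], default="dfs")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.indir / "isogenic_counts.tsv", sep="\t", index_col=0)
    cols = json.loads((args.indir / "truth.json").read_text())["isogenic_columns"]
    cpm = sg.cpm_normalize(counts)
    parental = sg.repressed_genes(cpm, cols["parental_drug"], cols["parental_vehicle"])
    ko_de = sg.differential_expression(cpm, cols["rb1_null_drug"],
                                       cols["rb1_null_vehicle"])
    seed_genes = sg.rb_dependency_filter(parental.index, ko_de)
    print(f"{len(parental)} drug-repressed genes in the parental line, "
          f"{len(seed_genes)} remain after the RB-dependency filter")

    clinical_expr = read_expression(args.indir / "clinical_expression.tsv",
                                    cohort_label="CLINSYN")
    model = sg.correlation_prune(seed_genes, clinical_expr)
    model.to_json(args.out / "signature.json")
    print(f"correlation prune removed {len(model.pruned_genes)}: "
          f"final signature has {len(model.genes)} genes")

    survival = {}
    for b in load_bundles(args.indir):
        table = sg.score_samples(b.expression, model)
        res = sg.stratify_and_compare(table, b.clinical, endpoint=args.endpoint)
        out = pd.DataFrame({"score": table.scores, "stratum": res["strata"]})
        write_results(out, args.out / f"{b.cohort_label}_scores.tsv")
        survival[b.cohort_label] = {
            "logrank_chi2": res["survival"].chi2,
            "logrank_p": res["survival"].p,
            "strata_sizes": res["strata"].value_counts().to_dict(),
        }
        print(f"{b.cohort_label}: three-strata {args.endpoint} "
              f"log-rank p={res['survival'].p:.3g}")
    (args.out / "stratified_survival.json").write_text(
        json.dumps(survival, indent=1))


if __name__ == "__main__":
    main()
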