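"""RB1-dosage differential expression and cis/trans classification.

Per eligible cohort (deep-deletion frequency >5% for the deep contrast,
het-loss frequency >10% for the het contrast): genome-wide DE against the
diploid class; then cross-cohort recurrence filtering (>66% deep, >33%
het), cis-fraction of the recurrent down-genes relative to 13q, and
hypergeometric overlap of the recurrent up-sets with the signature.
"""

import argparse
import json
from pathlib import Path

from rbpath import dosage_de as dd
from rbpath.core_io import write_results
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
    ap.add_argument("--out", type=Path, default=Path("results/dosage_de"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundles = list(load_bundles(args.indir))
    summary = {}
    recurrent = {}
    for contrast in ("diploid_vs_het", "diploid_vs_deep"):
        tables = {}
        for b in bundles:
            if not dd.cohort_eligible(b, contrast):
                continue
            t = dd.dosage_de(b, contrast=contrast)
            if t is None:
                continue
            tables[b.cohort_label] = t
            write_results(t, args.out / f"{b.cohort_label}_{contrast}.tsv")
        rec = dd.recurrence_filter(tables, contrast)
        recurrent[contrast] = rec
        entry = {"eligible_cohorts": rec.eligible_cohorts,
                 "n_up": len(rec.up), "n_down": len(rec.down)}
        if rec.down:
            frac, labels = dd.cis_fraction(rec.down, bundles[0].annotation)
            entry["cis_fraction_down"] = frac
            write_results(labels.to_frame(), args.out / f"{contrast}_down_cis.tsv")
            print(f"{contrast}: {len(rec.up)} up / {len(rec.down)} down recurrent; "
                  f"{frac:.0%} of down-genes are cis on 13q")
        else:
            print(f"{contrast}: {len(rec.up)} up / 0 down recurrent "
                  "(single-copy cis shifts sit below the fold-change filter)")
        summary[contrast] = entry

    with open(args.out / "recurrent_sets.gmt", "w") as fh:
        for contrast, rec in recurrent.items():
            for direction, genes in (("up", rec.up), ("down", rec.down)):
                if genes:
                    fh.write(f"{contrast}_{direction}\trecurrent "
                             f"{direction}-genes\t" + "\t".join(genes) + "\n")

    signature = SignatureModel.from_json(args.signature)
    universe = set(bundles[0].expression.gene_ids)
    overlaps = dd.overlap_tests(
        {"het_up": recurrent["diploid_vs_het"].up,
         "deep_up": recurrent["diploid_vs_deep"].up,
         "signature": [g for g in signature.genes if g in universe]},
        universe,
    )
    summary["overlaps"] = overlaps
    for pair, res in overlaps["pairwise"].items():
        print(f"overlap {pair}: k={res['overlap']} p={res['p']:.3g}")
    (args.out / "summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
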