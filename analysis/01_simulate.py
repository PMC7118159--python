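"""Simulate the synthetic pan-cancer study and write it to disk.

Emits, under results/synthetic/: one directory per tumor cohort in the
cBioPortal-style dialects (expression, discrete CNA, MAF-lite mutations,
clinical, annotation), the isogenic parental/RB1-null x vehicle/drug count
matrix, the clinical-cohort expression matrix used for correlation
pruning, a GMT of the planted gene sets, and the planted truth as JSON.
Every downstream script starts from these files.
"""

import argparse
import json
from pathlib import Path

from rbpath.core_io import write_bundle
from rbpath.simulate import (
    SyntheticConfig,
    generate_clinical_expression,
    generate_isogenic_experiment,
    generate_pancancer,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    bundles, truth = generate_pancancer(cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_bundle(b, args.out / b.cohort_label)
        n_alt = int((b.cna.values != 0).any(axis=0).sum())
        print(f"{b.cohort_label}: {len(b.sample_ids)} tumors, "
              f"{len(b.expression.gene_ids)} genes, {n_alt} with any CNA")

    counts, itruth = generate_isogenic_experiment(cfg)
    counts.to_csv(args.out / "isogenic_counts.tsv", sep="\t")
    clinical = generate_clinical_expression(cfg)
    clinical.values.to_csv(args.out / "clinical_expression.tsv", sep="\t")
    print(f"isogenic: {counts.shape[0]} genes x {counts.shape[1]} libraries; "
          f"clinical stand-in: {clinical.values.shape[1]} samples")

    with open(args.out / "gene_sets.gmt", "w") as fh:
        fh.write("program\tplanted RB-dependent program\t"
                 + "\t".join(truth.program_genes) + "\n")
        arm = [g for g in bundles[0].expression.gene_ids if g.startswith("ARMQ")]
        fh.write("arm13q\tsynthetic 13q genes\t" + "\t".join(arm) + "\n")
        null = [g for g in bundles[0].expression.gene_ids if g.startswith("NUL")]
        fh.write("null\tplanted null genes\t" + "\t".join(null) + "\n")

    truth_payload = {
        "modes": truth.modes,
        "program_genes": truth.program_genes,
        "rb_independent_genes": truth.rb_independent_genes,
        "decoy_genes": truth.decoy_genes,
        "hazard_coef": truth.hazard_coef,
        "censor_horizon": truth.censor_horizon,
        "isogenic_columns": itruth["columns"],
        "config": truth.config,
    }
    (args.out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    print(f"wrote study to {args.out}")


if __name__ == "__main__":
    main()
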