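"""Tabular I/O and validated cohort bundles.

All pipeline stages consume the containers defined here.  Files are plain
TSV in the dialects common to cBioPortal-style exports: an expression matrix
(first column gene id, header of sample ids), a discrete GISTIC copy-number
matrix with entries in {-2,-1,0,1,2}, a MAF-lite mutation table, a clinical
table, a gene annotation table (or BED), and GMT gene-set files.

Conventions fixed once for the whole package:

* gene coordinates are 1-based inclusive; BED input (0-based half-open) is
  converted on read;
* sample identifiers match by exact string equality after whitespace
  trimming — no TCGA-barcode truncation heuristics;
* missing clinical values are the literal string ``NA``; missing expression
  values are a fatal error because downstream correlation and bootstrap
  stages assume complete matrices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CnaMatrix",
    "MutationTable",
    "ClinicalTable",
    "GeneAnnotation",
    "GeneSetCollection",
    "CohortBundle",
    "BundleReport",
    "load_cohort_bundle",
    "read_expression",
    "read_cna",
    "read_mutations",
    "read_clinical",
    "read_annotation",
    "read_gmt",
    "write_results",
    "read_results",
]

VALID_CNA_CODES = frozenset({-2, -1, 0, 1, 2})
VARIANT_CLASSES = ("missense", "truncating", "inframe", "splice", "other")

#: MAF Variant_Classification spellings folded into the five internal classes.
_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "truncating",
    "frame_shift_del": "truncating",
    "frame_shift_ins": "truncating",
    "nonstop_mutation": "truncating",
    "truncating": "truncating",
    "in_frame_del": "inframe",
    "in_frame_ins": "inframe",
    "inframe": "inframe",
    "splice_site": "splice",
    "splice_region": "splice",
    "splice": "splice",
}


class BundleValidationError(ValueError):
    """Raised when an input file violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise BundleValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with a declared unit."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    unit: str = "log2"  # one of counts|cpm|log2|zscore
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.unit not in {"counts", "cpm", "log2", "zscore"}:
            raise BundleValidationError(f"unknown expression unit {self.unit!r}")
        self.values.index = pd.Index(
            _check_unique(self.values.index, "gene"), name="gene"
        )
        self.values.columns = pd.Index(
            _check_unique(self.values.columns, "sample"), name="sample"
        )
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise BundleValidationError(
                f"expression matrix {self.cohort_label!r} contains missing or "
                "non-finite values; complete matrices are required"
            )
        if self.unit in {"counts", "cpm"} and (arr < 0).any():
            raise BundleValidationError(f"negative values in a {self.unit} matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)].copy(), self.unit, self.cohort_label
        )


@dataclass
class CnaMatrix:
    """Genes x samples discrete copy-number calls.

    Entries use the five-level GISTIC code: -2 deep deletion, -1 heterozygous
    (shallow/single-copy) loss, 0 diploid, 1 gain, 2 amplification.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index = pd.Index(
            _check_unique(self.values.index, "gene"), name="gene"
        )
        self.values.columns = pd.Index(
            _check_unique(self.values.columns, "sample"), name="sample"
        )
        arr = self.values.to_numpy()
        bad = ~np.isin(arr, list(VALID_CNA_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BundleValidationError(
                f"malformed CNA code {arr[i, j]!r} at gene "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        self.values = self.values.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Iterable[str]) -> "CnaMatrix":
        return CnaMatrix(self.values.loc[:, list(samples)].copy())


@dataclass
class MutationTable:
    """MAF-lite rows of (sample_id, gene_id, variant_class)."""

    rows: pd.DataFrame  # columns: sample_id, gene_id, variant_class

    def __post_init__(self) -> None:
        required = ["sample_id", "gene_id", "variant_class"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise BundleValidationError(f"mutation table missing columns {missing}")
        self.rows = self.rows[required].copy()
        for col in ("sample_id", "gene_id"):
            self.rows[col] = self.rows[col].astype(str).str.strip()
        bad = ~self.rows["variant_class"].isin(VARIANT_CLASSES)
        if bad.any():
            raise BundleValidationError(
                f"unknown variant class {self.rows.loc[bad, 'variant_class'].iloc[0]!r}"
            )

    def subset_samples(self, samples: Iterable[str]) -> "MutationTable":
        keep = self.rows["sample_id"].isin(set(samples))
        return MutationTable(self.rows.loc[keep].reset_index(drop=True))


@dataclass
class ClinicalTable:
    """Per-sample cohort, subtype and survival endpoints.

    ``dfs``/``os`` carry disease-free and overall survival as
    (time in months, event flag); either may be missing (NaN) but an event
    flag is only meaningful alongside its time.
    """

    rows: pd.DataFrame  # index sample_id; cohort, subtype, dfs_months,
    # dfs_event, os_months, os_event

    def __post_init__(self) -> None:
        self.rows.index = pd.Index(
            _check_unique(self.rows.index, "sample"), name="sample"
        )
        for stem in ("dfs", "os"):
            t, e = f"{stem}_months", f"{stem}_event"
            times = self.rows[t]
            events = self.rows[e]
            if (times.dropna() < 0).any():
                raise BundleValidationError(f"negative {t}")
            orphan = events.notna() & times.isna()
            if orphan.any():
                raise BundleValidationError(
                    f"{e} present without {t} for sample "
                    f"{self.rows.index[orphan][0]!r}"
                )
            bad = ~events.dropna().isin([0, 1])
            if bad.any():
                raise BundleValidationError(f"{e} must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows.index)

    def subset_samples(self, samples: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.rows.loc[list(samples)].copy())

    def endpoint(self, which: str) -> pd.DataFrame:
        """Return (time, event) rows for endpoint ``dfs`` or ``os``, complete cases only."""
        if which not in {"dfs", "os"}:
            raise ValueError(f"endpoint must be 'dfs' or 'os', got {which!r}")
        sub = self.rows[[f"{which}_months", f"{which}_event"]].dropna()
        sub.columns = ["time", "event"]
        return sub


@dataclass
class GeneAnnotation:
    """Gene -> (chromosome, arm, start, end), 1-based inclusive coordinates."""

    rows: pd.DataFrame  # index gene; chrom, arm, start, end

    def __post_init__(self) -> None:
        self.rows.index = pd.Index(
            _check_unique(self.rows.index, "gene"), name="gene"
        )
        if (self.rows["start"] >= self.rows["end"]).any():
            g = self.rows.index[self.rows["start"] >= self.rows["end"]][0]
            raise BundleValidationError(f"start >= end for gene {g!r}")
        bad_arm = ~self.rows["arm"].isin(["p", "q"])
        if bad_arm.any():
            raise BundleValidationError(
                f"arm must be 'p' or 'q' for gene {self.rows.index[bad_arm][0]!r}"
            )

    def on_arm(self, chrom: str, arm: str) -> pd.DataFrame:
        """Genes on ``chrom``/``arm`` sorted by start coordinate."""
        sel = (self.rows["chrom"].astype(str) == str(chrom)) & (
            self.rows["arm"] == arm
        )
        return self.rows.loc[sel].sort_values("start")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content), insertion-ordered, members deduplicated."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            dedup = list(dict.fromkeys(members))
            if not dedup:
                raise BundleValidationError(f"gene set {name!r} is empty")
            cleaned[name] = dedup
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class BundleReport:
    """What load_cohort_bundle dropped while intersecting identifiers."""

    shared_samples: list[str]
    dropped: dict[str, list[str]]  # table name -> samples absent elsewhere


@dataclass
class CohortBundle:
    expression: ExpressionMatrix
    cna: CnaMatrix
    mutations: MutationTable
    clinical: ClinicalTable
    annotation: GeneAnnotation
    report: BundleReport | None = None

    @property
    def cohort_label(self) -> str:
        return self.expression.cohort_label

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


# ---------------------------------------------------------------------------
# readers


def read_expression(path, unit: str = "log2", cohort_label: str = "") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, unit=unit, cohort_label=cohort_label)


def read_cna(path) -> CnaMatrix:
    df = pd.read_csv(path, sep="\t")
    gene_col = "Hugo_Symbol" if "Hugo_Symbol" in df.columns else df.columns[0]
    df = df.set_index(gene_col)
    df = df.drop(columns=[c for c in ("Entrez_Gene_Id",) if c in df.columns])
    arr = df.to_numpy()
    if not np.isin(arr, list(VALID_CNA_CODES)).all():
        bad = np.argwhere(~np.isin(arr, list(VALID_CNA_CODES)))[0]
        raise BundleValidationError(
            f"{path}: malformed CNA code {arr[bad[0], bad[1]]!r} at gene "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    return CnaMatrix(df)


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t")
    rename = {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene_id",
        "Variant_Classification": "variant_class",
    }
    df = df.rename(columns=rename)
    df["variant_class"] = (
        df["variant_class"].astype(str).str.strip().str.lower().map(
            lambda v: _MAF_CLASS_MAP.get(v, v if v in VARIANT_CLASSES else "other")
        )
    )
    return MutationTable(df)


def read_clinical(path, cohort_label: str = "") -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample": str})
    df = df.set_index("sample")
    df.index = df.index.str.strip()
    for col in ("cohort", "subtype"):
        if col not in df.columns:
            df[col] = cohort_label if col == "cohort" else pd.NA
    for stem in ("dfs", "os"):
        tcol, scol = f"{stem}_months", f"{stem}_status"
        if tcol not in df.columns:
            df[tcol] = np.nan
        if scol in df.columns:
            df[f"{stem}_event"] = _parse_status(df[scol])
        elif f"{stem}_event" not in df.columns:
            df[f"{stem}_event"] = np.nan
    keep = ["cohort", "subtype", "dfs_months", "dfs_event", "os_months", "os_event"]
    return ClinicalTable(df[keep])


def _parse_status(col: pd.Series) -> pd.Series:
    """cBioPortal-style status strings ('1:Recurred', 'DECEASED', '0') -> 0/1."""

    def one(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip()
        if ":" in s:
            s = s.split(":", 1)[0]
        if s in {"0", "1", "0.0", "1.0"}:
            return int(float(s))
        low = s.lower()
        if low in {"deceased", "recurred", "progressed", "recurred/progressed", "event"}:
            return 1
        if low in {"living", "alive", "diseasefree", "disease free", "censored"}:
            return 0
        return np.nan

    return col.map(one)


def read_annotation(path) -> GeneAnnotation:
    """TSV (gene, chrom, arm, start, end; 1-based) or BED (converted on read)."""
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if path.suffix.lower() == ".bed" or (first and "\t" in first and "gene" not in first.lower()):
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene"],
        )
        df["start"] = df["start"] + 1  # BED is 0-based half-open
        df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
        df["arm"] = "q"  # BED has no arm column; caller may override
        df = df.set_index("gene")[["chrom", "arm", "start", "end"]]
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
        df = df.set_index("gene")[["chrom", "arm", "start", "end"]]
    return GeneAnnotation(df)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member...

    Preserves file order, deduplicates members within each line.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BundleValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, description, *members = fields
            sets[name] = [m for m in (x.strip() for x in members) if m]
            desc[name] = description
    return GeneSetCollection(sets, desc)


def load_cohort_bundle(
    expr_path,
    cna_path,
    mut_path,
    clinical_path,
    annotation_path,
    unit: str = "log2",
    cohort_label: str = "",
) -> CohortBundle:
    """Read the five tables and intersect their sample identifiers.

    Samples present in one table but not another are dropped and reported;
    an empty intersection is fatal.  Gene identifiers are matched
    case-sensitively and genes are left as-is per table (stages intersect
    genes as needed).
    """
    expr = read_expression(expr_path, unit=unit, cohort_label=cohort_label)
    cna = read_cna(cna_path)
    mut = read_mutations(mut_path)
    clin = read_clinical(clinical_path, cohort_label=cohort_label)
    ann = read_annotation(annotation_path)

    tables = {
        "expression": set(expr.sample_ids),
        "cna": set(cna.sample_ids),
        "clinical": set(clin.sample_ids),
    }
    shared = set.intersection(*tables.values())
    if not shared:
        raise BundleValidationError("no samples shared across expression/CNA/clinical")
    # canonical order: sorted, so the bundle is invariant to input column order
    shared_sorted = sorted(shared)
    dropped = {
        name: sorted(ids - shared) for name, ids in tables.items() if ids - shared
    }
    report = BundleReport(shared_samples=shared_sorted, dropped=dropped)
    return CohortBundle(
        expression=expr.subset_samples(shared_sorted),
        cna=cna.subset_samples(shared_sorted),
        mutations=mut.subset_samples(shared_sorted),
        clinical=clin.subset_samples(shared_sorted),
        annotation=ann,
        report=report,
    )


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write a cohort bundle in the on-disk dialects this module reads.

    Returns the path map; round-tripping through load_cohort_bundle
    reproduces the bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": outdir / "expression.tsv",
        "cna": outdir / "cna.tsv",
        "mut": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "annotation": outdir / "annotation.tsv",
    }
    bundle.expression.values.to_csv(paths["expr"], sep="\t")
    cna = bundle.cna.values.copy()
    cna.index.name = "Hugo_Symbol"
    cna.to_csv(paths["cna"], sep="\t")
    mut = bundle.mutations.rows.rename(columns={
        "sample_id": "Tumor_Sample_Barcode",
        "gene_id": "Hugo_Symbol",
        "variant_class": "Variant_Classification",
    })
    mut.to_csv(paths["mut"], sep="\t", index=False)
    clin = bundle.clinical.rows.copy()
    clin = clin.rename(columns={"dfs_event": "dfs_status", "os_event": "os_status"})
    clin.to_csv(paths["clinical"], sep="\t", na_rep="NA")
    bundle.annotation.rows.to_csv(paths["annotation"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# result serialization


def write_results(table: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a result table as TSV (NaN -> 'NA', repr-faithful floats) or JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        table.to_csv(path, sep="\t", na_rep="NA", float_format=None)
    elif format == "json":
        payload = {
            "index": [_json_safe(i) for i in table.index],
            "columns": list(map(str, table.columns)),
            "data": [[_json_safe(v) for v in row] for row in table.itertuples(index=False)],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")


def _json_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating, float)):
        return None if math.isnan(float(v)) else float(v)
    return v


def read_results(path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(
            payload["data"], index=payload["index"], columns=payload["columns"]
        )
    raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
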