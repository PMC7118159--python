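"""Synthetic pan-cancer cohorts with known planted structure.

Every analytic stage in this package has a recovery test; this module
generates the inputs those tests run on, without any external download.
Three generators mirror the three data sources the pipeline consumes:

``generate_pancancer``
    Multi-cohort tumor bundles.  Each tumor draws one latent RB-pathway
    mode — RB1 loss, CDKN2A deletion, CCND1 amplification, CDK4
    amplification, or none — which plants mutual exclusivity between RB1
    loss and the CDK4/6-deregulating modes and co-occurrence between the
    two amplifications.  RB1-loss tumors receive a contiguous deletion
    segment on a synthetic chromosome-13q (focal over RB1 or arm-level),
    shifting cis gene expression down by the dosage effects; a co-regulated
    transcriptional program activates when RB1 is lost; survival hazard
    scales with program activity.

``generate_isogenic_experiment``
    Negative-binomial RNA-seq counts for parental / RB1-null cells under
    vehicle / drug, with planted drug-repressed genes that are either
    RB-dependent (repressed in parental only) or RB-independent (repressed
    in both genotypes).

``generate_clinical_expression``
    A large breast-cancer-like expression matrix in which the program genes
    share a latent factor while "decoy" genes (drug-repressed in the cell
    line but not co-regulated in tumors) are uncorrelated — exercising the
    max-correlation pruning step.

Gene classes share names across generators (``PRG*`` program, ``DEC*``
decoys, ``IND*`` RB-independent, ``NUL*`` nulls, ``ARMQ*`` 13q genes) so a
signature derived from the isogenic experiment can be pruned on the
clinical matrix and scored on the tumor bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    ClinicalTable,
    CnaMatrix,
    CohortBundle,
    ExpressionMatrix,
    GeneAnnotation,
    MutationTable,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_pancancer",
           "generate_isogenic_experiment", "generate_clinical_expression"]

MODES = ("rb1_loss", "cdkn2a_del", "ccnd1_amp", "cdk4_amp", "none")
PATHWAY_GENES = ("CCND1", "CDK4", "CDKN2A", "RB1")

#: default per-cohort mode mixes; cohorts cycle through these so each is
#: dominated by a different lesion (mirrors tumor types clustering apart)
_DEFAULT_MODE_PROBS = (
    {"rb1_loss": 0.40, "cdkn2a_del": 0.10, "ccnd1_amp": 0.08, "cdk4_amp": 0.07, "none": 0.35},
    {"rb1_loss": 0.20, "cdkn2a_del": 0.40, "ccnd1_amp": 0.08, "cdk4_amp": 0.07, "none": 0.25},
    {"rb1_loss": 0.20, "cdkn2a_del": 0.10, "ccnd1_amp": 0.35, "cdk4_amp": 0.10, "none": 0.25},
    {"rb1_loss": 0.20, "cdkn2a_del": 0.10, "ccnd1_amp": 0.10, "cdk4_amp": 0.35, "none": 0.25},
)


@dataclass
class SyntheticConfig:
    """Planted parameters of the synthetic study.

    Defaults are the study conditions the recovery tests run under; see the
    methods note for the rationale behind each.
    """

    n_cohorts: int = 4
    n_samples: int = 200          # tumors per cohort
    arm_genes: int = 60           # genes on the synthetic 13q
    rb1_index: int = 30           # RB1's position within the arm
    brca2_index: int = 10         # marker analog position
    program_genes: int = 50       # co-regulated RB-dependent program
    n_decoys: int = 10            # drug-repressed but not co-regulated in tumors
    n_rb_independent: int = 20    # repressed regardless of RB1 genotype
    n_null_genes: int = 100
    mode_probs: tuple = _DEFAULT_MODE_PROBS  # cycled per cohort
    co_amp_prob: float = 0.3      # joint CCND1+CDK4 amplification
    background_event_rate: float = 0.02   # epsilon: per-gene sporadic events
    deep_fraction: float = 0.3    # rho: P(13q deletion is deep)
    focal_weight: float = 0.5     # lambda: focal vs arm-level segment mix
    rb1_mut_prob: float = 0.7     # truncating RB1 mutation when loss is shallow
    dosage_shift_het: float = 0.5     # d_het, log2 units
    dosage_shift_deep: float = 3.0    # d_deep
    amp_shift: float = 1.0            # cis gain for amplified oncogenes
    cdkn2a_feedback: float = 1.0      # CDKN2A elevation when RB1 is lost
    program_gain: float = 1.0         # beta: program activation on RB1 loss
    hazard_coef: float = 0.8          # beta_surv on standardized activity
    baseline_hazard: float = 0.01     # events per month at mean activity
    censor_horizon: float = 120.0     # uniform censoring upper bound (months)
    nb_dispersion: float = 0.005
    replicates: int = 2               # per isogenic arm
    isogenic_log2_fold: float = -2.0  # planted repression in the cell line
    n_clinical_samples: int = 2000
    program_correlation: float = 0.6  # shared-factor variance fraction
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("co_amp_prob", "background_event_rate", "deep_fraction",
                     "focal_weight", "rb1_mut_prob", "program_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_cohorts", "n_samples", "arm_genes", "program_genes",
                     "replicates", "n_clinical_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rb1_index < self.arm_genes:
            raise ValueError("rb1_index must index into the arm")
        for mp in self.mode_probs:
            total = sum(mp.get(m, 0.0) for m in MODES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mode probabilities sum to {total}, not 1")
            if any(p < 0 for p in mp.values()):
                raise ValueError("mode probabilities must be non-negative")

    # gene naming -----------------------------------------------------------
    @property
    def arm_gene_names(self) -> list[str]:
        names = [f"ARMQ{i + 1:03d}" for i in range(self.arm_genes)]
        names[self.rb1_index] = "RB1"
        names[self.brca2_index] = "BRCA2"
        return names

    @property
    def program_gene_names(self) -> list[str]:
        return [f"PRG{i + 1:03d}" for i in range(self.program_genes)]

    @property
    def decoy_gene_names(self) -> list[str]:
        return [f"DEC{i + 1:03d}" for i in range(self.n_decoys)]

    @property
    def independent_gene_names(self) -> list[str]:
        return [f"IND{i + 1:03d}" for i in range(self.n_rb_independent)]

    @property
    def null_gene_names(self) -> list[str]:
        return [f"NUL{i + 1:03d}" for i in range(self.n_null_genes)]

    @property
    def all_gene_names(self) -> list[str]:
        return (self.arm_gene_names + ["CDKN2A", "CCND1", "CDK4"]
                + self.program_gene_names + self.decoy_gene_names
                + self.independent_gene_names + self.null_gene_names)


@dataclass
class SyntheticTruth:
    """Planted parameters, recomputable from the emitted bundle."""

    modes: dict                       # cohort -> sample -> mode
    planted_odds_ratios: dict         # cohort -> {(geneA,geneB): OR from emitted calls}
    cis_segments: dict                # cohort -> sample -> [deleted 13q genes]
    program_genes: list[str]
    rb_independent_genes: list[str]
    decoy_genes: list[str]
    hazard_coef: float
    censor_horizon: float
    config: dict = field(default_factory=dict)


def _build_annotation(cfg: SyntheticConfig) -> GeneAnnotation:
    rows = []
    for i, g in enumerate(cfg.arm_gene_names):
        start = 20_000_000 + i * 1_000_000
        rows.append((g, "13", "q", start, start + 50_000))
    rows.append(("CDKN2A", "9", "p", 21_967_752, 21_995_301))
    rows.append(("CCND1", "11", "q", 69_455_873, 69_469_242))
    rows.append(("CDK4", "12", "q", 58_141_510, 58_149_796))
    others = (cfg.program_gene_names + cfg.decoy_gene_names
              + cfg.independent_gene_names + cfg.null_gene_names)
    for i, g in enumerate(others):
        chrom = str(1 + (i % 8))
        start = 10_000_000 + i * 500_000
        rows.append((g, chrom, "q", start, start + 40_000))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "arm", "start", "end"])
    return GeneAnnotation(df.set_index("gene"))


def _altered(cna_col: pd.Series, mutated: set, gene: str) -> bool:
    """'Altered' = amplification, deep deletion, or non-silent mutation."""
    return cna_col[gene] in (-2, 2) or gene in mutated


def generate_pancancer(cfg: SyntheticConfig) -> tuple[list[CohortBundle], SyntheticTruth]:
    """Simulate ``n_cohorts`` tumor bundles plus the planted truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.all_gene_names
    arm_names = cfg.arm_gene_names
    annotation = _build_annotation(cfg)

    bundles: list[CohortBundle] = []
    truth_modes: dict = {}
    truth_or: dict = {}
    truth_segments: dict = {}

    for ci in range(cfg.n_cohorts):
        cohort = f"SYN{ci + 1:02d}"
        mode_p = cfg.mode_probs[ci % len(cfg.mode_probs)]
        probs = np.array([mode_p.get(m, 0.0) for m in MODES])
        samples = [f"{cohort}-T{j + 1:04d}" for j in range(cfg.n_samples)]
        modes = [MODES[k] for k in rng.choice(len(MODES), size=cfg.n_samples, p=probs)]

        cna = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
        mut_rows: list[tuple[str, str, str]] = []
        segments: dict = {}
        rb1_lost = np.zeros(cfg.n_samples, dtype=bool)

        for j, (s, mode) in enumerate(zip(samples, modes)):
            if mode == "rb1_loss":
                rb1_lost[j] = True
                if rng.random() < cfg.focal_weight:
                    lo = rng.integers(0, cfg.rb1_index + 1)
                    hi = rng.integers(cfg.rb1_index, cfg.arm_genes)
                else:
                    lo, hi = 0, cfg.arm_genes - 1
                deep = rng.random() < cfg.deep_fraction
                code = -2 if deep else -1
                seg = arm_names[lo:hi + 1]
                cna.loc[seg, s] = code
                segments[s] = list(seg)
                if not deep and rng.random() < cfg.rb1_mut_prob:
                    mut_rows.append((s, "RB1", "truncating"))
            elif mode == "cdkn2a_del":
                cna.loc["CDKN2A", s] = -2
            elif mode == "ccnd1_amp":
                cna.loc["CCND1", s] = 2
                if rng.random() < cfg.co_amp_prob:
                    cna.loc["CDK4", s] = 2
            elif mode == "cdk4_amp":
                cna.loc["CDK4", s] = 2
                if rng.random() < cfg.co_amp_prob:
                    cna.loc["CCND1", s] = 2
            # sporadic background events on the four pathway genes
            for g in PATHWAY_GENES:
                if rng.random() < cfg.background_event_rate:
                    kind = rng.integers(0, 4)
                    if kind == 0 and cna.loc[g, s] == 0:
                        cna.loc[g, s] = 2
                    elif kind == 1 and cna.loc[g, s] == 0:
                        cna.loc[g, s] = -2
                    elif kind == 2 and cna.loc[g, s] == 0:
                        cna.loc[g, s] = -1  # passenger shallow loss
                    else:
                        mut_rows.append((s, g, "missense"))

        # expression: log2 scale, gene-specific baselines, cohort-wide noise
        base = rng.normal(8.0, 1.0, size=len(genes))
        expr = pd.DataFrame(
            base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), cfg.n_samples)),
            index=genes, columns=samples,
        )
        # cis dosage on every gene sitting inside an emitted CNA segment
        cna_arr = cna.to_numpy()
        expr_arr = expr.to_numpy()
        expr_arr = (expr_arr
                    + (cna_arr == -1) * (-cfg.dosage_shift_het)
                    + (cna_arr == -2) * (-cfg.dosage_shift_deep)
                    + (cna_arr == 2) * cfg.amp_shift)
        expr = pd.DataFrame(expr_arr, index=genes, columns=samples)
        # RB1 loss elevates CDKN2A (feedback) and activates the program
        expr.loc["CDKN2A", rb1_lost] += cfg.cdkn2a_feedback
        activity = cfg.program_gain * rb1_lost + rng.normal(0.0, 0.5, cfg.n_samples)
        expr.loc[cfg.program_gene_names] += activity[None, :]

        # survival: exponential with hazard tied to standardized activity
        z = (activity - activity.mean()) / (activity.std() if activity.std() > 0 else 1.0)
        hazard = cfg.baseline_hazard * np.exp(cfg.hazard_coef * z)
        t_dfs = rng.exponential(1.0 / hazard)
        c_dfs = rng.uniform(0.0, cfg.censor_horizon, cfg.n_samples)
        t_os = rng.exponential(1.0 / (0.8 * hazard))
        c_os = rng.uniform(0.0, cfg.censor_horizon, cfg.n_samples)
        clin = pd.DataFrame(
            {
                "cohort": cohort,
                "subtype": pd.NA,
                "dfs_months": np.minimum(t_dfs, c_dfs),
                "dfs_event": (t_dfs <= c_dfs).astype(int),
                "os_months": np.minimum(t_os, c_os),
                "os_event": (t_os <= c_os).astype(int),
            },
            index=pd.Index(samples, name="sample"),
        )

        mut = MutationTable(pd.DataFrame(mut_rows, columns=["sample_id", "gene_id", "variant_class"]))
        bundle = CohortBundle(
            expression=ExpressionMatrix(expr, unit="log2", cohort_label=cohort),
            cna=CnaMatrix(cna),
            mutations=mut,
            clinical=ClinicalTable(clin),
            annotation=annotation,
        )
        bundles.append(bundle)
        truth_modes[cohort] = dict(zip(samples, modes))
        truth_segments[cohort] = segments
        truth_or[cohort] = _realized_odds_ratios(bundle)

    truth = SyntheticTruth(
        modes=truth_modes,
        planted_odds_ratios=truth_or,
        cis_segments=truth_segments,
        program_genes=cfg.program_gene_names,
        rb_independent_genes=cfg.independent_gene_names,
        decoy_genes=cfg.decoy_gene_names,
        hazard_coef=cfg.hazard_coef,
        censor_horizon=cfg.censor_horizon,
        config={k: v for k, v in asdict(cfg).items() if k != "mode_probs"},
    )
    return bundles, truth


def _realized_odds_ratios(bundle: CohortBundle) -> dict:
    """Odds ratios of the emitted alteration calls for every pathway pair."""
    mut_by_sample: dict[str, set] = {}
    for row in bundle.mutations.rows.itertuples(index=False):
        mut_by_sample.setdefault(row.sample_id, set()).add(row.gene_id)
    calls = {}
    for g in PATHWAY_GENES:
        calls[g] = np.array([
            _altered(bundle.cna.values[s], mut_by_sample.get(s, set()), g)
            for s in bundle.sample_ids
        ])
    out = {}
    for i, gi in enumerate(PATHWAY_GENES):
        for gj in PATHWAY_GENES[i + 1:]:
            a = int((calls[gi] & calls[gj]).sum())
            b = int((calls[gi] & ~calls[gj]).sum())
            c = int((~calls[gi] & calls[gj]).sum())
            d = int((~calls[gi] & ~calls[gj]).sum())
            out[(gi, gj)] = (a * d) / (b * c) if b * c > 0 else float("nan")
    return out


def generate_isogenic_experiment(cfg: SyntheticConfig):
    """Counts for {parental, rb1_null} x {vehicle, drug} x replicates.

    Program and decoy genes are repressed (default log2 fold -2) only in the
    drug-treated parental line; RB-independent genes are repressed under
    drug in both genotypes; everything else is null.  Counts are
    negative-binomial via the gamma-Poisson mixture; dispersion 0 degrades
    to plain Poisson.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    genes = (cfg.program_gene_names + cfg.decoy_gene_names
             + cfg.independent_gene_names + cfg.null_gene_names)
    conditions = [
        ("parental", "vehicle"), ("parental", "drug"),
        ("rb1_null", "vehicle"), ("rb1_null", "drug"),
    ]
    columns = [f"{g}_{t}_{r + 1}" for g, t in conditions for r in range(cfg.replicates)]
    base_mean = np.exp(rng.normal(np.log(1000.0), 0.5, size=len(genes)))
    fold = 2.0 ** cfg.isogenic_log2_fold
    rb_dependent = set(cfg.program_gene_names) | set(cfg.decoy_gene_names)
    rb_independent = set(cfg.independent_gene_names)

    counts = np.zeros((len(genes), len(columns)), dtype=int)
    col = 0
    for genotype, treatment in conditions:
        for _ in range(cfg.replicates):
            mu = base_mean.copy()
            if treatment == "drug":
                for gi, g in enumerate(genes):
                    if g in rb_independent:
                        mu[gi] *= fold
                    elif g in rb_dependent and genotype == "parental":
                        mu[gi] *= fold
            if cfg.nb_dispersion > 0:
                lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
            else:
                lam = mu
            counts[:, col] = rng.poisson(lam)
            col += 1

    table = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=columns)
    truth = {
        "rb_dependent_repressed": sorted(rb_dependent),
        "rb_independent_repressed": sorted(rb_independent),
        "log2_fold": cfg.isogenic_log2_fold,
        "columns": {
            f"{g}_{t}": [f"{g}_{t}_{r + 1}" for r in range(cfg.replicates)]
            for g, t in conditions
        },
    }
    return table, truth


def generate_clinical_expression(cfg: SyntheticConfig) -> ExpressionMatrix:
    """Large clinical-cohort expression stand-in for correlation pruning.

    Program genes load on one latent factor with shared-variance fraction
    ``program_correlation`` (pairwise correlation equals that fraction in
    expectation); decoys and nulls are independent noise.
    """
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    genes = (cfg.program_gene_names + cfg.decoy_gene_names
             + cfg.independent_gene_names + cfg.null_gene_names)
    n = cfg.n_clinical_samples
    samples = [f"CLIN-{j + 1:05d}" for j in range(n)]
    factor = rng.normal(0.0, 1.0, size=n)
    c = cfg.program_correlation
    values = np.empty((len(genes), n))
    program = set(cfg.program_gene_names)
    for gi, g in enumerate(genes):
        noise = rng.normal(0.0, 1.0, size=n)
        if g in program and c > 0:
            values[gi] = np.sqrt(c) * factor + np.sqrt(1.0 - c) * noise
        else:
            values[gi] = noise
    values += 8.0  # arbitrary log2 baseline
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                     columns=pd.Index(samples, name="sample")),
        unit="log2", cohort_label="CLINSYN",
    )
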