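"""Signature derivation chain, scoring, and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rbpath import signature as sg
from rbpath.core_io import ClinicalTable, ExpressionMatrix
from rbpath.simulate import SyntheticConfig, generate_pancancer


# ---------------------------------------------------------------------------
# CPM


def test_cpm_definition():
    counts = pd.DataFrame({"L1": [10, 999_990]}, index=["G1", "G2"])
    cpm = sg.cpm_normalize(counts)
    assert cpm.loc["G1", "L1"] == pytest.approx(10.0)


def test_cpm_column_proportions():
    counts = pd.DataFrame({"L1": [90, 10]}, index=["G1", "G2"])
    cpm = sg.cpm_normalize(counts)
    assert cpm["L1"].tolist() == [900_000.0, 100_000.0]
    assert cpm.sum(axis=0).tolist() == [1e6]


def test_cpm_zero_library_errors():
    with pytest.raises(ValueError, match="library"):
        sg.cpm_normalize(pd.DataFrame({"L1": [0, 0]}, index=["G1", "G2"]))


# ---------------------------------------------------------------------------
# differential expression / repression filter


def _cpm_matrix(treated_level, control_level, n_genes=1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cols = ["t1", "t2", "c1", "c2"]
    data = np.empty((n_genes, 4))
    data[:, :2] = treated_level + rng.normal(0, noise, (n_genes, 2))
    data[:, 2:] = control_level + rng.normal(0, noise, (n_genes, 2))
    return pd.DataFrame(data, index=[f"G{i}" for i in range(n_genes)], columns=cols)


def test_log2_fold_change_quarter():
    # pseudocount-negligible CPM levels: 2500 vs 10000 -> log2 FC ~ -2
    cpm = _cpm_matrix(2500.0, 10000.0, noise=20.0)
    de = sg.differential_expression(cpm, ["t1", "t2"], ["c1", "c2"])
    assert de.loc["G0", "log2_fc"] == pytest.approx(-2.0, abs=0.05)


def test_unchanged_gene_excluded():
    cpm = _cpm_matrix(1000.0, 1000.0, noise=5.0)
    hits = sg.repressed_genes(cpm, ["t1", "t2"], ["c1", "c2"])
    assert len(hits) == 0


def test_repression_recovery_on_isogenic(isogenic):
    counts, truth = isogenic
    cpm = sg.cpm_normalize(counts)
    cols = truth["columns"]
    hits = sg.repressed_genes(cpm, cols["parental_drug"], cols["parental_vehicle"])
    planted = set(truth["rb_dependent_repressed"]) | set(truth["rb_independent_repressed"])
    sensitivity = len(set(hits.index) & planted) / len(planted)
    assert sensitivity >= 0.9
    false_hits = set(hits.index) - planted
    assert len(false_hits) <= 0.05 * len(cpm)


# ---------------------------------------------------------------------------
# RB-dependency filter


def test_dependency_filter_rules():
    ko = pd.DataFrame(
        {"log2_fc": [-2.0, -0.1, -2.0], "p": [0.01, 0.8, 0.2]},
        index=["both_down", "parental_only", "ko_not_significant"],
    )
    seed = sg.rb_dependency_filter(
        ["both_down", "parental_only", "ko_not_significant", "absent"], ko
    )
    assert seed == ["parental_only", "ko_not_significant", "absent"]


def test_dependency_filter_excludes_planted_independent(isogenic):
    counts, truth = isogenic
    cpm = sg.cpm_normalize(counts)
    cols = truth["columns"]
    hits = sg.repressed_genes(cpm, cols["parental_drug"], cols["parental_vehicle"])
    ko_de = sg.differential_expression(cpm, cols["rb1_null_drug"], cols["rb1_null_vehicle"])
    seed = sg.rb_dependency_filter(hits.index, ko_de)
    assert not set(seed) & set(truth["rb_independent_repressed"])


# ---------------------------------------------------------------------------
# correlation pruning


def test_prune_hand_example():
    # A,B perfectly correlated; C independent noise: max_corrs ~ {1,1,0},
    # mean ~ 2/3, C is pruned
    rng = np.random.default_rng(0)
    n = 500
    a = rng.normal(size=n)
    expr = ExpressionMatrix(pd.DataFrame(
        {"A": a, "B": a * 2 + 1, "C": rng.normal(size=n)}
    ).T.set_axis([f"S{i}" for i in range(n)], axis=1))
    model = sg.correlation_prune(["A", "B", "C"], expr)
    assert model.genes == ["A", "B"] and model.pruned_genes == ["C"]
    assert model.max_correlation["A"] == pytest.approx(1.0)


def test_prune_equal_correlations_keeps_all():
    # exact boundary: all pairwise correlations equal (affine copies), so
    # every max_corr equals the mean and nothing is pruned
    rng = np.random.default_rng(1)
    a = rng.normal(size=100)
    expr = ExpressionMatrix(pd.DataFrame(
        {"A": a, "B": 2 * a, "C": a - 5, "D": 0.5 * a + 1}
    ).T.set_axis([f"S{i}" for i in range(100)], axis=1))
    model = sg.correlation_prune(["A", "B", "C", "D"], expr)
    assert model.genes == ["A", "B", "C", "D"] and model.pruned_genes == []


def test_prune_removes_decoys_keeps_program(default_config, clinical_expr):
    seed = default_config.program_gene_names + default_config.decoy_gene_names
    model = sg.correlation_prune(seed, clinical_expr)
    assert set(model.genes) == set(default_config.program_gene_names)
    assert set(model.pruned_genes) == set(default_config.decoy_gene_names)


def test_prune_missing_genes_dropped_with_notice(clinical_expr):
    with pytest.warns(UserWarning, match="absent"):
        model = sg.correlation_prune(
            ["PRG001", "PRG002", "NOT_A_GENE"], clinical_expr
        )
    assert "NOT_A_GENE" in model.pruned_genes


# ---------------------------------------------------------------------------
# scoring


def test_score_zero_for_cohort_mean_sample():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(5, 9))
    X = np.hstack([X, X.mean(axis=1, keepdims=True)])  # last sample at the mean
    expr = ExpressionMatrix(pd.DataFrame(
        X, index=[f"G{i}" for i in range(5)], columns=[f"S{i}" for i in range(10)]
    ))
    table = sg.score_samples(expr, [f"G{i}" for i in range(5)])
    assert table.scores["S9"] == pytest.approx(0.0, abs=1e-12)


def test_score_invariant_to_affine_gene_rescaling():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(4, 20))
    expr1 = ExpressionMatrix(pd.DataFrame(
        X, index=list("ABCD"), columns=[f"S{i}" for i in range(20)]
    ))
    X2 = X.copy()
    X2[0] = X2[0] * 7.5 - 3.0
    expr2 = ExpressionMatrix(pd.DataFrame(
        X2, index=list("ABCD"), columns=[f"S{i}" for i in range(20)]
    ))
    s1 = sg.score_samples(expr1, list("ABCD")).scores
    s2 = sg.score_samples(expr2, list("ABCD")).scores
    assert np.allclose(s1, s2)


def test_score_invariant_to_sample_duplication():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(4, 15))
    expr1 = ExpressionMatrix(pd.DataFrame(
        X, index=list("ABCD"), columns=[f"S{i}" for i in range(15)]
    ))
    expr2 = ExpressionMatrix(pd.DataFrame(
        np.hstack([X, X]), index=list("ABCD"),
        columns=[f"S{i}" for i in range(15)] + [f"D{i}" for i in range(15)],
    ))
    s1 = sg.score_samples(expr1, list("ABCD")).scores
    s2 = sg.score_samples(expr2, list("ABCD")).scores
    assert np.allclose(s1.to_numpy(), s2.iloc[:15].to_numpy())


def test_score_low_coverage_errors(pancancer, derived_signature):
    bundles, _ = pancancer
    fake = sg.SignatureModel(
        genes=["NOPE1", "NOPE2", "PRG001"],
        seed_genes=["NOPE1", "NOPE2", "PRG001"], pruned_genes=[],
    )
    with pytest.raises(ValueError, match="signature genes present"):
        sg.score_samples(bundles[0].expression, fake)


def test_program_active_tumors_score_higher(pancancer, derived_signature):
    bundles, truth = pancancer
    b = bundles[0]
    table = sg.score_samples(b.expression, derived_signature)
    modes = truth.modes[b.cohort_label]
    active = np.array([modes[s] == "rb1_loss" for s in table.scores.index])
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(active, table.scores.to_numpy()) >= 0.9


# ---------------------------------------------------------------------------
# stratification


def test_stratify_quartile_example():
    scores = pd.Series(
        [1, 2, 3, 4, 5, 6, 7, 8], index=[f"S{i}" for i in range(8)], dtype=float
    )
    strata = sg.stratify(scores)
    assert list(strata[scores <= 2]) == ["low25", "low25"]
    assert list(strata[scores >= 7]) == ["high25", "high25"]
    assert (strata[(scores > 2) & (scores < 7)] == "mid50").all()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(8, 200), st.integers(0, 2**31 - 1))
def test_stratum_sizes_near_quartiles(n, seed):
    rng = np.random.default_rng(seed)
    scores = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
    strata = sg.stratify(scores)
    counts = strata.value_counts()
    assert abs(counts.get("low25", 0) - int(n * 0.25)) <= 1
    assert abs(counts.get("high25", 0) - int(n * 0.25)) <= 1


def test_stratify_identical_scores_errors():
    scores = pd.Series(np.ones(20), index=[f"S{i}" for i in range(20)])
    with pytest.raises(ValueError, match="tied scores"):
        sg.stratify(scores)


def test_high_stratum_has_worse_survival(pancancer, derived_signature):
    bundles, _ = pancancer
    b = bundles[0]
    table = sg.score_samples(b.expression, derived_signature)
    res = sg.stratify_and_compare(table, b.clinical, endpoint="dfs")
    assert res["survival"].p < 0.05
    final = {g: c["survival"].iloc[-1] for g, c in res["survival"].curves.items()}
    assert final["high25"] < final["low25"]


def test_no_survival_separation_without_hazard_link():
    cfg = SyntheticConfig(seed=17, n_cohorts=1, n_samples=400, arm_genes=12,
                          rb1_index=6, brca2_index=2, program_genes=10,
                          n_null_genes=10, n_decoys=0, n_rb_independent=0,
                          hazard_coef=0.0, n_clinical_samples=50)
    bundles, truth = generate_pancancer(cfg)
    b = bundles[0]
    table = sg.score_samples(b.expression, truth.program_genes)
    res = sg.stratify_and_compare(table, b.clinical, endpoint="dfs")
    assert res["survival"].p > 0.05


def test_full_chain_recovers_program(default_config, derived_signature, pancancer):
    _, truth = pancancer
    prog = set(truth.program_genes)
    got = set(derived_signature.genes)
    jaccard = len(prog & got) / len(prog | got)
    assert jaccard >= 0.8
    assert not got & set(truth.rb_independent_genes)
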