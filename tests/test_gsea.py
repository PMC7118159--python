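"""Bootstrap cutoffs, weight formula, pre-ranked GSEA vs brute force."""

import numpy as np
import pandas as pd
import pytest

from rbpath import gsea, signature as sg


# ---------------------------------------------------------------------------
# oracles


def brute_force_es(weights, in_set):
    """Running-sum extremum computed with explicit loops."""
    n = len(weights)
    nh = sum(in_set)
    hit_total = sum(abs(w) for w, m in zip(weights, in_set) if m)
    running, best = 0.0, 0.0
    for w, m in zip(weights, in_set):
        if m:
            running += abs(w) / hit_total
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_cutoffs(cc, n_boot, seed, level=0.95):
    """Independent resampler honouring the documented generator contract."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cc), size=(n_boot, len(cc)))
    pooled = [cc[i] for row in idx for i in row]
    alpha = (1 - level) / 2
    return tuple(np.quantile(pooled, [alpha, 1 - alpha]))


# ---------------------------------------------------------------------------
# gene-wise correlation


def test_signature_gene_correlates_with_score(pancancer, derived_signature):
    bundles, truth = pancancer
    b = bundles[0]
    table = sg.score_samples(b.expression, derived_signature)
    prof = gsea.genewise_correlation(b.expression, table.scores)
    sig_cc = prof.loc[[g for g in derived_signature.genes if g in prof.index], "CC"]
    null_cc = prof.loc[[g for g in prof.index if g.startswith("NUL")], "CC"]
    assert sig_cc.mean() > 0.5
    assert abs(null_cc.mean()) < 0.1


def test_permuted_scores_destroy_correlation(pancancer, derived_signature):
    bundles, _ = pancancer
    b = bundles[0]
    table = sg.score_samples(b.expression, derived_signature)
    rng = np.random.default_rng(0)
    shuffled = pd.Series(
        rng.permutation(table.scores.to_numpy()), index=table.scores.index
    )
    prof = gsea.genewise_correlation(b.expression, shuffled)
    assert abs(prof["CC"].mean()) < 0.05


def test_constant_gene_excluded():
    from rbpath.core_io import ExpressionMatrix

    expr = ExpressionMatrix(pd.DataFrame(
        {"S%d" % i: [1.0, float(i), float(i) * 2] for i in range(10)},
        index=["CONST", "G1", "G2"],
    ))
    scores = pd.Series(np.arange(10.0), index=[f"S{i}" for i in range(10)])
    prof = gsea.genewise_correlation(expr, scores)
    assert "CONST" not in prof.index and {"G1", "G2"} <= set(prof.index)


# ---------------------------------------------------------------------------
# bootstrap cutoffs


def test_cutoffs_match_brute_force_resampler():
    cc = np.array([-0.5, -0.2, 0.0, 0.1, 0.3, 0.45, 0.5, -0.1, 0.2, 0.25, -0.3, 0.05])
    prof = pd.DataFrame({"CC": cc, "p_val": 0.01},
                        index=[f"G{i}" for i in range(len(cc))])
    cuts = gsea.bootstrap_cutoffs(prof, n_boot=4, seed=123)
    lo, hi = brute_force_cutoffs(cc, n_boot=4, seed=123)
    assert cuts.lower == pytest.approx(lo, abs=1e-12)
    assert cuts.upper == pytest.approx(hi, abs=1e-12)


def test_cutoffs_degenerate_profile():
    prof = pd.DataFrame({"CC": [0.3] * 12, "p_val": 0.001},
                        index=[f"G{i}" for i in range(12)])
    cuts = gsea.bootstrap_cutoffs(prof, n_boot=200, seed=0)
    assert cuts.lower == cuts.upper == pytest.approx(0.3)
    sel = gsea.apply_cutoffs(prof, cuts)
    assert (sel["selected"] == "none").all()  # nothing strictly beyond


def test_cutoffs_symmetric_for_symmetric_distribution():
    rng = np.random.default_rng(8)
    cc = np.concatenate([rng.uniform(-0.8, 0.8, 1000)])
    cc = np.concatenate([cc, -cc])  # exactly symmetric
    prof = pd.DataFrame({"CC": cc, "p_val": 0.01},
                        index=[f"G{i}" for i in range(len(cc))])
    cuts = gsea.bootstrap_cutoffs(prof, n_boot=10_000, seed=1)
    # Monte-Carlo error of a 2.5% quantile of ~4e7 pooled draws is tiny, but
    # draws are dependent across resamples; allow a generous 3-SE-style band
    assert abs(cuts.lower + cuts.upper) < 0.02


def test_cutoffs_converged_at_default_n_boot():
    rng = np.random.default_rng(9)
    prof = pd.DataFrame({"CC": rng.normal(0, 0.3, 2000).clip(-1, 1), "p_val": 0.01},
                        index=[f"G{i}" for i in range(2000)])
    c1 = gsea.bootstrap_cutoffs(prof, n_boot=10_000, seed=2)
    c2 = gsea.bootstrap_cutoffs(prof, n_boot=100_000, seed=3)
    assert abs(c1.lower - c2.lower) < 0.01 and abs(c1.upper - c2.upper) < 0.01


def test_selection_sets_disjoint_and_beyond_cutoffs(pancancer, derived_signature):
    bundles, _ = pancancer
    b = bundles[0]
    table = sg.score_samples(b.expression, derived_signature)
    prof = gsea.genewise_correlation(b.expression, table.scores)
    cuts = gsea.bootstrap_cutoffs(prof, seed=5)
    sel = gsea.apply_cutoffs(prof, cuts)
    pos = sel[sel["selected"] == "positive"]
    neg = sel[sel["selected"] == "negative"]
    assert not set(pos.index) & set(neg.index)
    assert (pos["CC"] > cuts.upper).all() and (pos["p_val"] < 0.05).all()
    assert (neg["CC"] < cuts.lower).all() and (neg["p_val"] < 0.05).all()


def test_too_few_genes_errors():
    prof = pd.DataFrame({"CC": [0.1] * 5, "p_val": 0.01},
                        index=[f"G{i}" for i in range(5)])
    with pytest.raises(ValueError):
        gsea.bootstrap_cutoffs(prof, seed=0)


# ---------------------------------------------------------------------------
# weights


def test_weight_formula():
    prof = pd.DataFrame(
        {"CC": [0.5, -0.4, 0.2], "p_val": [0.01, 0.1, 1.0]},
        index=pd.Index(["A", "B", "C"], name="gene"),
    )
    ranked = gsea.gsea_weights(prof, selected_only=False)
    assert ranked.loc["A", "W"] == pytest.approx(1.0)   # 0.5 * 2
    assert ranked.loc["B", "W"] == pytest.approx(-0.4)  # -0.4 * 1
    assert ranked.loc["C", "W"] == pytest.approx(0.0)   # log10(1) = 0


def test_weight_zero_p_floored():
    prof = pd.DataFrame({"CC": [0.5], "p_val": [0.0]},
                        index=pd.Index(["A"], name="gene"))
    ranked = gsea.gsea_weights(prof, selected_only=False)
    assert bool(ranked.loc["A", "p_floored"])
    assert ranked.loc["A", "W"] == pytest.approx(0.5 * 300)


def test_weight_ordering_invariant_to_input_order():
    rng = np.random.default_rng(3)
    prof = pd.DataFrame(
        {"CC": rng.uniform(-1, 1, 30), "p_val": rng.uniform(0.001, 0.5, 30)},
        index=pd.Index([f"G{i:02d}" for i in range(30)], name="gene"),
    )
    r1 = gsea.gsea_weights(prof, selected_only=False)
    r2 = gsea.gsea_weights(prof.sample(frac=1, random_state=4), selected_only=False)
    assert list(r1.index) == list(r2.index)


# ---------------------------------------------------------------------------
# pre-ranked GSEA


def _ranked(weights, names=None):
    names = names or [f"G{i}" for i in range(len(weights))]
    return pd.DataFrame(
        {"W": weights}, index=pd.Index(names, name="gene")
    )


def test_es_matches_brute_force_small_lists():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(4, 13)
        weights = np.round(rng.uniform(-3, 3, n), 2)
        order = np.argsort(-weights)
        weights = weights[order]
        members = rng.choice(n, size=rng.integers(2, n), replace=False)
        in_set = np.zeros(n, dtype=bool)
        in_set[members] = True
        es, _ = gsea.running_sum_es(weights, in_set)
        assert es == pytest.approx(brute_force_es(weights, in_set), abs=1e-12)


def test_top_gene_singleton_es():
    # 4-gene list, weights 4,3,2,1, set = {top gene}: running sum peaks at
    # +1 immediately
    weights = np.array([4.0, 3.0, 2.0, 1.0])
    in_set = np.array([True, False, False, False])
    es, peak = gsea.running_sum_es(weights, in_set)
    assert es == pytest.approx(brute_force_es(weights, in_set))
    assert es == pytest.approx(1.0) and peak == 0


def test_whole_list_set_skipped():
    ranked = _ranked(np.linspace(3, -3, 12))
    res = gsea.preranked_gsea(ranked, {"ALL": list(ranked.index)}, n_perm=10, seed=0)
    assert res == []


def test_small_set_skipped():
    ranked = _ranked(np.linspace(3, -3, 12))
    res = gsea.preranked_gsea(ranked, {"ONE": [ranked.index[0]]}, n_perm=10, seed=0)
    assert res == []


def test_permutation_p_matches_enumeration_rate():
    # small space: compare sampled p with the exhaustive same-sign rate
    import itertools

    weights = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0, -3.0])
    ranked = _ranked(weights)
    members = [ranked.index[0], ranked.index[1]]
    res = gsea.preranked_gsea(ranked, {"TOP": members}, n_perm=2000, seed=1)[0]
    es_all = []
    for combo in itertools.combinations(range(10), 2):
        mask = np.zeros(10, dtype=bool)
        mask[list(combo)] = True
        es_all.append(gsea.running_sum_es(weights, mask)[0])
    same = [e for e in es_all if np.sign(e) == np.sign(res.es)]
    exact = sum(abs(e) >= abs(res.es) for e in same) / len(same)
    se = np.sqrt(max(exact * (1 - exact), 1 / 2000) / 2000)
    assert abs(res.p - max(exact, 1 / 2001)) <= 3 * se + 1e-9


def test_planted_program_enriched(pancancer, derived_signature):
    bundles, truth = pancancer
    b = bundles[0]
    table = sg.score_samples(b.expression, derived_signature)
    prof = gsea.genewise_correlation(b.expression, table.scores)
    cuts = gsea.bootstrap_cutoffs(prof, seed=5)
    ranked = gsea.gsea_weights(gsea.apply_cutoffs(prof, cuts))
    sets = {
        "program": truth.program_genes,
        "arm13q": [g for g in b.expression.gene_ids if g.startswith("ARMQ")],
    }
    res = {r.set_name: r for r in gsea.preranked_gsea(ranked, sets, n_perm=500, seed=2)}
    assert res["program"].es > 0 and res["program"].p < 0.05
    assert res["arm13q"].es < 0  # cis-deleted genes anti-correlate with the score


def test_gsea_deterministic_under_seed():
    rng = np.random.default_rng(5)
    ranked = _ranked(np.sort(rng.uniform(-2, 2, 40))[::-1])
    sets = {"S": list(ranked.index[5:15])}
    r1 = gsea.preranked_gsea(ranked, sets, n_perm=200, seed=9)[0]
    r2 = gsea.preranked_gsea(ranked, sets, n_perm=200, seed=9)[0]
    assert (r1.es, r1.nes, r1.p) == (r2.es, r2.nes, r2.p)


def test_es_cross_checked_against_gseapy():
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(13)
    n = 200
    names = [f"G{i:03d}" for i in range(n)]
    weights = np.sort(rng.normal(0, 1, n))[::-1]
    ranked = _ranked(weights, names)
    members = list(rng.choice(names, 25, replace=False))
    rnk = pd.Series(weights, index=names)
    pre = gseapy.prerank(
        rnk=rnk, gene_sets={"S": members}, permutation_num=10,
        weight=1.0, min_size=2, max_size=500, seed=0, outdir=None, no_plot=True,
    )
    es_ref = float(pre.res2d["ES"].iloc[0])
    in_set = np.isin(names, members)
    es, _ = gsea.running_sum_es(weights, in_set)
    assert es == pytest.approx(es_ref, abs=5e-3)


# ---------------------------------------------------------------------------
# clustering of correlation profiles


def test_cluster_two_anticorrelated_programs():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(4)
    base = rng.uniform(0.5, 0.9, 6)
    up = np.tile(base, (20, 1)) + rng.normal(0, 0.02, (20, 6))
    down = -np.tile(base, (15, 1)) + rng.normal(0, 0.02, (15, 6))
    cc = pd.DataFrame(np.vstack([up, down]),
                      index=[f"G{i}" for i in range(35)],
                      columns=[f"C{i}" for i in range(6)])
    labels, mask, degenerate = gsea.cluster_correlation_matrix(cc, k=2)
    true = [0] * 20 + [1] * 15
    assert adjusted_rand_score(true, labels) == 1.0
    assert not degenerate and not mask.any().any()


def test_cluster_identical_rows_degenerate():
    cc = pd.DataFrame(np.ones((6, 3)), index=[f"G{i}" for i in range(6)])
    _, _, degenerate = gsea.cluster_correlation_matrix(cc, k=2)
    assert degenerate


def test_cluster_missing_values_imputed_with_mask():
    rng = np.random.default_rng(6)
    cc = pd.DataFrame(rng.normal(size=(10, 3)),
                      index=[f"G{i}" for i in range(10)])
    cc.iloc[0, 0] = np.nan
    labels, mask, _ = gsea.cluster_correlation_matrix(cc, k=3)
    assert mask.iloc[0, 0] and mask.to_numpy().sum() == 1
    assert len(labels) == 10


def test_cluster_kmeans_mode_deterministic():
    rng = np.random.default_rng(2)
    cc = pd.DataFrame(rng.normal(size=(30, 4)),
                      index=[f"G{i}" for i in range(30)])
    l1, _, _ = gsea.cluster_correlation_matrix(cc, k=5, method="kmeans", seed=3)
    l2, _, _ = gsea.cluster_correlation_matrix(cc, k=5, method="kmeans", seed=3)
    assert l1.equals(l2)


def test_cluster_k_exceeds_rows():
    cc = pd.DataFrame(np.eye(3))
    with pytest.raises(ValueError):
        gsea.cluster_correlation_matrix(cc, k=5)
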