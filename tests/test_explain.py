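import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from cnvpatho.annotate import FeatureMatrix, apply_impute, fit_impute
from cnvpatho.core import CNVType, Label
from cnvpatho.explain import (differential_top_features, element_proportions,
                              feature_group_stats, kruskal_wallis,
                              mann_whitney_u, pairwise_posthoc,
                              rank_features_by_shap, shap_attributions,
                              shap_dependence)
from cnvpatho.model import Hyperparameters, TaskSpec, train_model
from cnvpatho.registry import FeatureDef, FeatureRegistry

from oracles import brute_mannwhitney


def _registry(n):
    return FeatureRegistry(
        [FeatureDef("length", "length", "cnv_itself")] +
        [FeatureDef(f"f{i}", "count", "genes", "protein_coding")
         for i in range(1, n)])


def _fit(X, y, nrounds=30, seed=0):
    m = FeatureMatrix(_registry(X.shape[1]), [f"r{i}" for i in range(len(X))], X)
    m = apply_impute(m, fit_impute(m))
    model = train_model(m, y, TaskSpec("binary", CNVType.LOSS),
                        Hyperparameters(nrounds=nrounds), seed=seed)
    return model, m


def _planted(n=300, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = [Label.PATHOGENIC if i % 2 else Label.BENIGN for i in range(n)]
    X[:, 0] += 3.0 * np.array([l is Label.PATHOGENIC for l in y])
    return X, y


# ---------------------------------------------------------------------------
# SHAP
# ---------------------------------------------------------------------------

def test_shap_additivity_binary_and_multiclass():
    X, y = _planted()
    model, m = _fit(X, y)
    att = shap_attributions(model, m)
    assert att.additivity_error() <= 1e-6

    rng = np.random.default_rng(1)
    X5 = rng.normal(size=(200, 4))
    classes = list(TaskSpec("five_tier", CNVType.LOSS).classes)
    y5 = [classes[i % 5] for i in range(200)]
    m5 = FeatureMatrix(_registry(4), [f"r{i}" for i in range(200)], X5)
    m5 = apply_impute(m5, fit_impute(m5))
    model5 = train_model(m5, y5, TaskSpec("five_tier", CNVType.LOSS),
                         Hyperparameters(nrounds=20), seed=1)
    att5 = shap_attributions(model5, m5)
    assert att5.values.ndim == 3
    assert att5.additivity_error() <= 1e-6


def test_single_informative_feature_carries_all_attribution():
    X, y = _planted()
    X[:, 1:] = 0.0  # only feature 0 varies
    model, m = _fit(X, y)
    att = shap_attributions(model, m)
    assert np.abs(att.values[:, 1:]).max() == 0.0
    assert np.abs(att.values[:, 0]).max() > 0.0
    assert rank_features_by_shap(att, 1) == ["length"]


def test_rank_ties_break_by_registry_order():
    att_names = ["length", "f1", "f2"]
    from cnvpatho.explain import AttributionMatrix
    att = AttributionMatrix(att_names, np.zeros((5, 3)), np.zeros(5), np.zeros(5))
    assert rank_features_by_shap(att, 10) == att_names  # all-zero: registry order


def test_rank_top_k_truncates():
    X, y = _planted()
    model, m = _fit(X, y)
    att = shap_attributions(model, m)
    assert len(rank_features_by_shap(att, 2)) == 2
    assert len(rank_features_by_shap(att, 99)) == 4  # more than available: all


def test_rank_invariant_to_row_order():
    X, y = _planted()
    model, m = _fit(X, y)
    att = shap_attributions(model, m)
    perm = np.random.default_rng(0).permutation(len(X))
    att2 = shap_attributions(model, m.subset(perm))
    assert rank_features_by_shap(att) == rank_features_by_shap(att2)


def test_dependence_monotone_signal_has_positive_association_and_crossing():
    X, y = _planted(600)
    model, m = _fit(X, y, nrounds=60)
    att = shap_attributions(model, m)
    pairs, threshold = shap_dependence(att, "length", m)
    from scipy.stats import spearmanr
    rho, _ = spearmanr(pairs["value"], pairs["attribution"])
    assert rho > 0.5
    assert threshold is not None


def test_dependence_constant_feature_all_zero_attribution():
    X, y = _planted()
    X[:, 2] = 5.0
    model, m = _fit(X, y)
    att = shap_attributions(model, m)
    pairs, threshold = shap_dependence(att, "f2", m)
    assert np.abs(pairs["attribution"]).max() == 0.0
    assert threshold is None


def test_dependence_unknown_feature_rejected():
    X, y = _planted(60)
    model, m = _fit(X, y, nrounds=5)
    att = shap_attributions(model, m)
    with pytest.raises(KeyError):
        shap_dependence(att, "nope", m)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mannwhitney_derived_example():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)


def test_mannwhitney_identical_samples():
    u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert u == 3 * 3 / 2
    assert p == 1.0


def test_mannwhitney_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for nx, ny in [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)]:
        for _ in range(3):
            x = rng.integers(0, 6, nx).astype(float)  # ties likely
            y = rng.integers(0, 6, ny).astype(float)
            u, p = mann_whitney_u(x, y)
            u_o, p_o = brute_mannwhitney(list(x), list(y))
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)


def test_mannwhitney_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(1)
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    _, p = mann_whitney_u(x, y)
    assert p == pytest.approx(scipy_mwu(x, y, method="exact",
                                        alternative="two-sided").pvalue)


def test_mannwhitney_large_sample_approximation_reasonable():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = rng.normal(loc=1.2, size=40)
    _, p = mann_whitney_u(x, y)
    ref = scipy_mwu(x, y, alternative="two-sided").pvalue
    assert p == pytest.approx(ref, rel=0.05)
    assert p < 0.01


def test_mannwhitney_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis and post hoc
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups_h_zero():
    h, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
    assert h == 0.0 and p == 1.0


def test_kruskal_monotone_with_mannwhitney_at_k2():
    rng = np.random.default_rng(0)
    stats = []
    for shift in (0.0, 0.5, 1.5):
        x = rng.normal(size=20)
        y = rng.normal(loc=shift, size=20)
        h, _ = kruskal_wallis([x, y])
        u, _ = mann_whitney_u(x, y)
        stats.append((abs(u - 200.0), h))  # |U - n1n2/2| vs H
    devs, hs = zip(*sorted(stats))
    assert list(hs) == sorted(hs)  # H grows with the U deviation


def test_posthoc_count_and_bonferroni_cap():
    rng = np.random.default_rng(0)
    groups = {c: rng.normal(size=8) for c in "abc"}
    table = pairwise_posthoc(groups)
    assert len(table) == 3  # k(k-1)/2 with k=3
    assert (table["p_bonferroni"] <= 1.0).all()
    # multiplier is the number of comparisons
    raw_scaled = np.minimum(1.0, table["p"] * 3)
    np.testing.assert_allclose(table["p_bonferroni"], raw_scaled)


def test_feature_group_stats_vs_benign_reference(toy_bundle, toy_cnvs, registry):
    from cnvpatho.annotate import annotate_cnvs
    m = annotate_cnvs(toy_cnvs, toy_bundle, registry)
    labels = [r.label for r in toy_cnvs]
    gs = feature_group_stats(m, labels, "length")
    assert gs.reference == "benign"
    assert set(gs.tests["group"]) == {"uncertain_significance", "pathogenic"}
    assert ((gs.tests["p"] >= 0) & (gs.tests["p"] <= 1)).all()
    assert gs.kruskal_p <= 1.0


# ---------------------------------------------------------------------------
# element proportions and differential features
# ---------------------------------------------------------------------------

def test_element_proportions_sum_to_one_and_pure_group(hand_bundle):
    from conftest import make_cnv
    pseudo_only = make_cnv("1", 400, 500, label=Label.BENIGN, rid="x")
    mixed = make_cnv("1", 100, 300, label=Label.PATHOGENIC, rid="y")
    frac = element_proportions([pseudo_only, mixed], hand_bundle)
    assert frac.loc["benign", "pseudogene"] == 1.0
    np.testing.assert_allclose(frac.sum(axis=1), 1.0)


def test_element_proportions_undefined_group_flagged(hand_bundle):
    from conftest import make_cnv
    nothing = make_cnv("2", 5000, 5100, label=Label.BENIGN, rid="z")
    frac = element_proportions([nothing], hand_bundle)
    assert frac.loc["benign"].isna().all()


def test_planted_morbid_enrichment_visible_in_proportions(toy_bundle, toy_cnvs):
    frac = element_proportions(toy_cnvs, toy_bundle)
    assert frac.loc["pathogenic", "Morbid_gene"] > frac.loc["benign", "Morbid_gene"]


def test_differential_top_features_finds_planted_signal():
    rng = np.random.default_rng(4)
    n = 200
    X = rng.poisson(2.0, size=(n, 6)).astype(float)
    y = [Label.PATHOGENIC if i % 2 else Label.BENIGN for i in range(n)]
    X[:, 0] += 40.0 * np.array([l is Label.PATHOGENIC for l in y])  # planted
    reg = _registry(6)
    m = FeatureMatrix(reg, [f"r{i}" for i in range(n)], X)
    selected, sub = differential_top_features(m, y, top_k=3)
    assert "length" in selected  # the planted column
    # transform: log10(x+1), so a zero count stays zero
    assert sub.drop(columns="label").min().min() >= 0.0


def test_differential_removes_all_zero_rows():
    X = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 0.0], [0.0, 0.0]])
    y = [Label.BENIGN, Label.BENIGN, Label.PATHOGENIC, Label.PATHOGENIC]
    m = FeatureMatrix(_registry(2), list("abcd"), X)
    selected, sub = differential_top_features(m, y, top_k=2)
    assert set(sub.index) == {"b", "c"}  # all-zero rows a, d dropped


def test_differential_constant_features_rank_last():
    X = np.column_stack([np.full(40, 7.0),
                         np.r_[np.zeros(20), np.ones(20)]])
    y = [Label.BENIGN] * 20 + [Label.PATHOGENIC] * 20
    m = FeatureMatrix(_registry(2), [f"r{i}" for i in range(40)], X)
    selected, _ = differential_top_features(m, y, top_k=1)
    assert selected == ["f1"]  # the informative one; constant ranked last
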