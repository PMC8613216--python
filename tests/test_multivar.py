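"""Feature tables, PCA/HC, PLS-DA/sPLS-DA and AUROC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from hrdcc.multivar import (
    PLSDAClassifier,
    auroc_one_vs_rest,
    build_feature_table,
    hier_cluster,
    merge_phases,
    pca,
    plsda_fit,
    preprocess,
    splsda_fit,
    top_discriminating_features,
)
from hrdcc.simulate import EffectSpec, simulate_cohort
from hrdcc.workflows import group_c_design


def _table(x, phases=None):
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
    if phases is not None:
        df.insert(0, "phase", phases)
    return df


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def test_preprocess_standardized_unchanged():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 4))
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    out, centers, scales = preprocess(_table(x))
    np.testing.assert_allclose(out.to_numpy(dtype=float), x, atol=1e-12)


def test_preprocess_drops_constant_column():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(50, 3))
    x[:, 1] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        out, centers, scales = preprocess(_table(x))
    assert "f1" not in out.columns
    with pytest.raises(ValueError):
        preprocess(_table(np.ones((10, 2))))


def test_preprocess_round_trip():
    rng = np.random.default_rng(2)
    x = rng.normal(5, 3, size=(40, 3))
    out, centers, scales = preprocess(_table(x))
    back = out.to_numpy(dtype=float) * scales.to_numpy() + centers.to_numpy()
    np.testing.assert_allclose(back, x, rtol=1e-10)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_rank_one():
    rng = np.random.default_rng(3)
    x = np.zeros((30, 4))
    x[:, 2] = rng.normal(size=30)
    res = pca(_table(x), n_components=2)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)
    assert abs(res.loadings.loc["f2", "PC1"]) == pytest.approx(1.0, abs=1e-9)
    assert res.top_features["PC1"][0] == "f2"


def test_pca_eigenvalue_ratio_two_features():
    """Correlation rho=0.6: eigenvalues 1.6/0.4 -> variance ratio 0.8/0.2."""
    rng = np.random.default_rng(4)
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    x = rng.multivariate_normal([0, 0], cov, size=4000)
    table, _, _ = preprocess(_table(x))
    res = pca(table, n_components=2)
    assert res.explained_variance_ratio[0] == pytest.approx(0.8, abs=0.03)
    assert res.explained_variance_ratio[1] == pytest.approx(0.2, abs=0.03)


def test_pca_scores_uncorrelated_and_loadings_orthonormal():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(60, 5)) @ rng.normal(size=(5, 5))
    res = pca(_table(x), n_components=4)
    s = res.scores.to_numpy()
    c = np.cov(s.T)
    off = c - np.diag(np.diag(c))
    assert np.abs(off).max() < 1e-8 * max(1.0, np.abs(np.diag(c)).max())
    l = res.loadings.to_numpy()
    np.testing.assert_allclose(l.T @ l, np.eye(4), atol=1e-9)
    assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)


def test_pca_n_components_validation():
    with pytest.raises(ValueError):
        pca(_table(np.random.default_rng(0).normal(size=(5, 3))), n_components=5)


def test_pca_implanted_late_effects_drive_pc1():
    """Late-phase shifts on intM and CD8T make them top PC1 contributors."""
    design = group_c_design(n_animals=4)
    effects = (EffectSpec("intM", "C", ("late",), 2.5),
               EffectSpec("CD8T", "C", ("late",), 2.5))
    res = simulate_cohort(design, effects, seed=5, n_events=500, panels=("myeloid",))
    wide = res.truth.pivot_table(index=["animal", "day"], columns="population",
                                 values="true_proportion").reset_index(drop=True)
    table, _, _ = preprocess(wide)
    out = pca(table, n_components=2)
    top3 = out.top_features["PC1"][:3]
    assert "intM" in top3
    assert "CD8T" in top3


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def test_hier_cluster_two_blobs():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 0.1, size=(10, 3))
    b = rng.normal(10, 0.1, size=(12, 3))
    res = hier_cluster(_table(np.vstack([a, b])), k=2)
    assert len(set(res.labels[:10])) == 1
    assert len(set(res.labels[10:])) == 1
    assert res.labels[0] != res.labels[-1]


def test_hier_cluster_duplicated_row_and_monotone_heights():
    x = np.tile([1.0, 2.0, 3.0], (6, 1))
    res = hier_cluster(_table(x), k=2)
    assert res.linkage_matrix[:, 2].max() == 0.0
    rng = np.random.default_rng(7)
    res2 = hier_cluster(_table(rng.normal(size=(25, 4))), k=3)
    heights = res2.linkage_matrix[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)  # Ward is monotone
    with pytest.raises(ValueError):
        hier_cluster(_table(x), k=10)


# ---------------------------------------------------------------------------
# PLS-DA / sPLS-DA
# ---------------------------------------------------------------------------


def _separable(n=40, p=6, seed=8):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    y = np.where(x[:, 0] + 0.1 * rng.normal(size=n) > 0, "pos", "neg")
    x[y == "pos", 0] += 4.0
    return x, y


def test_plsda_separable_training_accuracy():
    x, y = _separable()
    model = plsda_fit(x, y, n_components=2)
    assert (model.predict(x) == y).all()


def test_plsda_requires_two_classes_and_enough_rows():
    x, _ = _separable()
    with pytest.raises(ValueError, match="classes"):
        plsda_fit(x, np.repeat("a", len(x)), n_components=2)
    with pytest.raises(ValueError, match="samples"):
        plsda_fit(x[:3], np.array(["a", "b", "a"]), n_components=3)


def test_splsda_keepx_all_equals_dense():
    x, y = _separable(n=50, p=8)
    dense = plsda_fit(x, y, n_components=3)
    sparse_off = splsda_fit(x, y, n_components=3, keep_x=(8, 8, 8))
    np.testing.assert_allclose(sparse_off.x_weights_, dense.x_weights_, atol=1e-8)
    np.testing.assert_allclose(sparse_off.coef_, dense.coef_, atol=1e-8)
    also = splsda_fit(x, y, n_components=3, keep_x="all")
    np.testing.assert_allclose(also.x_weights_, dense.x_weights_, atol=1e-8)


def test_splsda_budget_respected():
    x, y = _separable(n=60, p=10)
    model = splsda_fit(x, y, n_components=3, keep_x=(5, 5, 5))
    for j in range(model.n_components_):
        assert np.count_nonzero(model.x_weights_[:, j]) <= 5


def test_splsda_single_informative_feature():
    """With one informative feature and keepX=1, that feature is selected;
    cross-checked against exhaustive single-feature screening."""
    rng = np.random.default_rng(9)
    n = 60
    x = rng.normal(size=(n, 7))
    y = np.repeat(["a", "b"], n // 2)
    x[y == "b", 4] += 3.0
    model = splsda_fit(x, y, n_components=1, keep_x=(1,))
    assert model.selected_features_[0] == [4]
    # oracle: feature with the largest |correlation| with the class indicator
    ind = (y == "b").astype(float)
    corrs = [abs(np.corrcoef(x[:, j], ind)[0, 1]) for j in range(7)]
    assert int(np.argmax(corrs)) == 4


def test_plsda_matches_sklearn_dense_predictions():
    """Dense PLS-DA predictions equal sklearn's NIPALS PLS regression on the
    same one-hot response."""
    x, y = _separable(n=45, p=6, seed=10)
    model = plsda_fit(x, y, n_components=3, scale=True)
    classes, idx = np.unique(y, return_inverse=True)
    yy = np.zeros((len(y), 2))
    yy[np.arange(len(y)), idx] = 1.0
    ref = PLSRegression(n_components=3, scale=True).fit(x, yy)
    np.testing.assert_allclose(model.decision_function(x), ref.predict(x), atol=1e-6)


def test_plsda_score_orthogonality():
    x, y = _separable(n=50, p=9, seed=11)
    model = plsda_fit(x, y, n_components=3)
    t = model.x_scores_
    g = t.T @ t
    off = g - np.diag(np.diag(g))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(g)).max()


def test_plsda_first_component_matches_covariance_scan():
    """On a 3-feature toy set the first X-weight direction matches the
    dominant covariance direction found by brute-force angular scan."""
    rng = np.random.default_rng(12)
    n = 200
    x = rng.normal(size=(n, 3))
    y = np.where(x[:, 1] > 0, "hi", "lo")
    model = plsda_fit(x, y, n_components=1, scale=False)
    # brute force over directions in the (f0, f1, f2) unit sphere
    ind = np.where(y == "hi", 1.0, 0.0)
    ind = ind - ind.mean()
    xc = x - x.mean(0)
    best, best_cov = None, -1
    for theta in np.linspace(0, np.pi, 181):
        for phi in np.linspace(0, np.pi, 181):
            w = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                          np.cos(theta)])
            cv = abs((xc @ w) @ ind)
            if cv > best_cov:
                best, best_cov = w, cv
    w1 = model.x_weights_[:, 0]
    cos = abs(best @ w1)
    assert cos > 0.999


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------


class _Fixed:
    """Minimal fitted-model stand-in with prescribed decision scores."""

    def __init__(self, scores, classes):
        self._scores = np.asarray(scores, dtype=float)
        self.classes_ = np.asarray(classes)

    def decision_function(self, X):
        return self._scores

    def get_params(self, deep=True):  # pragma: no cover - clone support
        return {}


def test_auroc_full_separation():
    scores = np.array([[0.9], [0.8], [0.7], [0.1]])
    scores = np.hstack([scores, 1 - scores])
    y = np.array(["p", "p", "n", "n"])
    res = auroc_one_vs_rest(_Fixed(scores, ["p", "n"]), np.zeros((4, 1)), y)
    assert res.auroc["p"] == 1.0


def test_auroc_hand_example_three_quarters():
    # positives {0.9, 0.4}, negatives {0.6, 0.2}: 3 of 4 concordant pairs
    scores = np.array([[0.9], [0.4], [0.6], [0.2]])
    scores = np.hstack([scores, -scores])
    y = np.array(["p", "p", "n", "n"])
    res = auroc_one_vs_rest(_Fixed(scores, ["p", "n"]), np.zeros((4, 1)), y)
    assert res.auroc["p"] == pytest.approx(0.75)


def test_auroc_equals_trapezoid_of_curve():
    rng = np.random.default_rng(13)
    n = 200
    s = rng.normal(size=n)
    y = np.where(rng.random(n) < 1 / (1 + np.exp(-s)), "p", "n")
    scores = np.column_stack([s, -s])
    res = auroc_one_vs_rest(_Fixed(scores, ["p", "n"]), np.zeros((n, 1)), y)
    fpr, tpr, _ = res.curves["p"]
    assert res.auroc["p"] == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


def test_auroc_label_permutation_null():
    """Mean LOO AUROC over label permutations sits at 0.5 -/+ 0.1."""
    rng = np.random.default_rng(14)
    x = rng.normal(size=(24, 6))
    y0 = np.repeat(["a", "b", "c"], 8)
    aucs = []
    for _ in range(100):
        y = rng.permutation(y0)
        model = PLSDAClassifier(n_components=2).fit(x, y)
        res = auroc_one_vs_rest(model, x, y, loo=True)
        aucs.append(np.nanmean(list(res.auroc.values())))
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_auroc_missing_class_warns():
    x, y = _separable(n=30, p=4, seed=15)
    model = plsda_fit(x, y, n_components=2)
    y2 = np.where(y == "pos", "pos", "pos")
    with pytest.warns(UserWarning, match="absent"):
        res = auroc_one_vs_rest(model, x, y2)
    assert "neg" not in res.auroc


def test_top_discriminating_features():
    rng = np.random.default_rng(16)
    n = 60
    x = rng.normal(size=(n, 8))
    y = np.repeat(["a", "b"], n // 2)
    x[y == "b", 3] += 3.0
    names = [f"f{i}" for i in range(8)]
    model = splsda_fit(x, y, n_components=2, keep_x=(5, 5))
    ranked = top_discriminating_features(model, names, per_component=5)
    assert ranked[0][1] == "f3"
    per_comp = {}
    for comp, name, w in ranked:
        per_comp.setdefault(comp, []).append(name)
    for comp, feats in per_comp.items():
        assert len(feats) <= 5
    # permutation equivariance: shuffle columns, same named ranking
    perm = rng.permutation(8)
    model2 = splsda_fit(x[:, perm], y, n_components=2, keep_x=(5, 5))
    ranked2 = top_discriminating_features(model2, [names[i] for i in perm],
                                          per_component=5)
    assert ranked2[0][1] == "f3"


# ---------------------------------------------------------------------------
# feature table plumbing
# ---------------------------------------------------------------------------


def test_merge_phases_relabels():
    df = pd.DataFrame({"phase": ["pre1", "pre2", "post1", "post2", "late"]})
    out = merge_phases(df)
    assert list(out.phase) == ["pre", "pre", "post", "post", "late"]


def test_build_feature_table_selection():
    records = pd.DataFrame({
        "animal": ["A1", "A1"], "day": [0, 0], "group": ["A", "A"],
        "phase": ["pre", "pre"], "fluid": ["blood", "milk"],
        "viability": [95.0, 93.0],
        "immature_neutrophil_pct": [5.0, 6.0],
        "pct_live_neutrophils": [28.0, 31.0],
    })
    lab = pd.DataFrame({"animal": ["A1"], "day": [0], "group": ["A"],
                        "phase": ["pre"], "haptoglobin": [0.2]})
    blood = build_feature_table(records, feature_set="blood")
    assert "blood_pct_live_neutrophils" in blood.columns
    assert not any(c.startswith("milk_") for c in blood.columns)
    allf = build_feature_table(records, lab, feature_set="all")
    for col in ("blood_viability", "milk_viability", "lab_haptoglobin"):
        assert col in allf.columns
    with pytest.raises(ValueError):
        build_feature_table(records, feature_set="plasma")
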