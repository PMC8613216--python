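"""Unsupervised and supervised analysis of HRDCC feature tables.

Feature tables have one row per (animal, day) with HRDCC percentages,
viability and (optionally) external-laboratory biomarkers, and a treatment
``phase`` label.  The analysis stack mirrors a standard immunophenotyping
workflow: PCA and Ward hierarchical clustering to explore phase structure,
then PLS-DA / sparse PLS-DA (per-component feature budgets, "keepX") with
one-vs-rest AUROC — optionally under leave-one-out cross-validation — to
find the most discriminating subpopulations.

The discriminant model is a scikit-learn style estimator
(:class:`PLSDAClassifier`): NIPALS latent-variable extraction on a one-hot
class response with per-component soft-thresholding of the X-weight vector
when a ``keep_x`` budget is set.  ``plsda_fit`` / ``splsda_fit`` are thin
wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "preprocess",
    "pca",
    "PCAResult",
    "hier_cluster",
    "HCResult",
    "PLSDAClassifier",
    "plsda_fit",
    "splsda_fit",
    "auroc_one_vs_rest",
    "ROCResult",
    "top_discriminating_features",
    "build_feature_table",
    "merge_phases",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("animal", "group", "day", "phase")


# ---------------------------------------------------------------------------
# feature-table plumbing
# ---------------------------------------------------------------------------


def merge_phases(df: pd.DataFrame, mapping: dict | None = None) -> pd.DataFrame:
    """Relabel phases before modeling (e.g. pre1 + pre2 -> pre)."""
    if mapping is None:
        mapping = {"pre1": "pre", "pre2": "pre", "post1": "post", "post2": "post"}
    out = df.copy()
    out["phase"] = out["phase"].map(lambda p: mapping.get(p, p))
    return out


def build_feature_table(records: pd.DataFrame, lab_table: pd.DataFrame | None = None,
                        feature_set: str = "all") -> pd.DataFrame:
    """Wide feature table from HRDCC records (and an optional lab table).

    One row per (animal, day); feature columns are prefixed ``blood_``,
    ``milk_`` or ``lab_``; ``feature_set`` in {"blood", "milk", "lab",
    "all"} selects which blocks are included.  Rows with missing values in
    the selected block are dropped.
    """
    if feature_set not in ("blood", "milk", "lab", "all"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    pieces = []
    meta_cols = [c for c in METADATA_COLUMNS if c in records.columns]
    for fluid in ("blood", "milk"):
        if feature_set not in (fluid, "all"):
            continue
        sub = records[records["fluid"] == fluid]
        if sub.empty:
            continue
        feat_cols = [c for c in sub.columns
                     if c.startswith("pct_live_") or c in ("viability", "immature_neutrophil_pct")]
        block = sub[meta_cols + feat_cols].copy()
        block = block.rename(columns={c: f"{fluid}_{c}" for c in feat_cols})
        pieces.append(block.set_index(["animal", "day"]))
    if lab_table is not None and feature_set in ("lab", "all"):
        lab_cols = [c for c in lab_table.columns if c not in METADATA_COLUMNS]
        block = lab_table[[c for c in METADATA_COLUMNS if c in lab_table.columns] + lab_cols]
        block = block.rename(columns={c: f"lab_{c}" for c in lab_cols})
        pieces.append(block.set_index(["animal", "day"]))
    if not pieces:
        raise ValueError(f"no data available for feature set {feature_set!r}")
    out = pieces[0]
    for extra in pieces[1:]:
        dup = [c for c in extra.columns if c in out.columns]
        out = out.join(extra.drop(columns=dup), how="inner")
    out = out.reset_index().dropna()
    return out


def _split_features(table: pd.DataFrame):
    feats = [c for c in table.columns if c not in METADATA_COLUMNS]
    return table[feats].to_numpy(dtype=float), feats


def preprocess(table: pd.DataFrame):
    """Column-wise center and unit-variance scale the numeric feature columns.

    Zero-variance columns are dropped with a warning.  Returns
    ``(scaled_table, centers, scales)``; metadata columns pass through.
    """
    x, feats = _split_features(table)
    centers = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.ones(x.shape[1])
    keep = scales > 0
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    if not keep.all():
        dropped = [f for f, k in zip(feats, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    feats = [f for f, k in zip(feats, keep) if k]
    scaled = (x[:, keep] - centers[keep]) / scales[keep]
    out = table[[c for c in METADATA_COLUMNS if c in table.columns]].copy()
    out[feats] = scaled
    return out, pd.Series(centers[keep], index=feats), pd.Series(scales[keep], index=feats)


# ---------------------------------------------------------------------------
# unsupervised
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # samples x components
    top_features: dict  # component -> features ranked by squared loading


def pca(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA (full SVD) of a preprocessed feature table.

    Per-feature contributions to a component are its squared loadings.
    """
    x, feats = _split_features(table)
    max_nc = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_nc:
        raise ValueError(f"n_components={n_components} exceeds limit {max_nc}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    comps = [f"PC{i+1}" for i in range(n_components)]
    loadings = pd.DataFrame(model.components_.T, index=feats, columns=comps)
    top = {c: list(loadings[c].pow(2).sort_values(ascending=False).index) for c in comps}
    return PCAResult(loadings, model.explained_variance_ratio_,
                     pd.DataFrame(scores, columns=comps, index=table.index), top)


@dataclass
class HCResult:
    linkage_matrix: np.ndarray
    labels: np.ndarray


def hier_cluster(table: pd.DataFrame, k: int = 2, distance: str = "euclidean",
                 linkage: str = "ward") -> HCResult:
    """Agglomerative clustering (default Euclidean/Ward) with a flat cut at k."""
    x, _ = _split_features(table)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if k > x.shape[0]:
        raise ValueError("k cannot exceed the number of rows")
    z = scipy_linkage(x, method=linkage, metric=distance)
    labels = fcluster(z, k, criterion="maxclust")
    return HCResult(z, labels)


# ---------------------------------------------------------------------------
# PLS-DA / sPLS-DA
# ---------------------------------------------------------------------------


def _soft_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest |w| (stable ties: first column wins) and
    soft-shrink them by the largest discarded magnitude."""
    p = w.size
    if keep >= p:
        return w
    order = np.argsort(-np.abs(w), kind="stable")
    lam = np.abs(w[order[keep]])
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    mask = np.zeros(p, dtype=bool)
    mask[order[:keep]] = True
    out[~mask] = 0.0
    return out


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis with optional per-component sparsity.

    NIPALS extraction of latent variables maximizing the covariance of X-
    and Y-scores on a centered one-hot class response; X is deflated per
    component.  With ``keep_x`` set (int, or one int per component) the
    X-weight vector is soft-thresholded each iteration so at most
    ``keep_x`` features carry non-zero weight — the sparse PLS-DA of the
    mixOmics tradition.  Prediction assigns the class with the maximum
    predicted response ("max.dist").

    Parameters
    ----------
    n_components : int, default 3
    keep_x : None, int or sequence of int, default None
        Per-component feature budget; None (or >= n_features) gives the
        dense model.
    scale : bool, default True
        Center and unit-variance scale X (fitted on the training data).
    max_iter, tol :
        NIPALS inner-loop controls.

    Attributes (after fit)
    ----------------------
    classes_, x_weights_, x_loadings_, y_loadings_, x_scores_, coef_,
    selected_features_ (list per component, by column index).
    """

    def __init__(self, n_components: int = 3, keep_x=None, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-9):
        self.n_components = n_components
        self.keep_x = keep_x
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def _keep_list(self, p: int):
        if self.keep_x is None:
            return [p] * self.n_components
        if np.isscalar(self.keep_x):
            budget = [int(self.keep_x)] * self.n_components
        else:
            budget = [int(k) for k in self.keep_x]
            if len(budget) != self.n_components:
                raise ValueError("keep_x must have one entry per component")
        for k in budget:
            if k < 1 or k > p:
                raise ValueError(f"keep_x entries must lie in [1, {p}]")
        return budget

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        if n < self.n_components + 2:
            raise ValueError("need at least n_components + 2 samples")
        budget = self._keep_list(p)

        self._x_mean = X.mean(axis=0)
        self._x_std = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self._x_std = np.where(self._x_std > 0, self._x_std, 1.0)
        Xw = (X - self._x_mean) / self._x_std
        Y = np.zeros((n, self.classes_.size))
        Y[np.arange(n), y_idx] = 1.0
        self._y_mean = Y.mean(axis=0)
        Yw = Y - self._y_mean

        h = self.n_components
        W = np.zeros((p, h))
        Pl = np.zeros((p, h))
        C = np.zeros((self.classes_.size, h))
        T = np.zeros((n, h))
        for comp in range(h):
            u = Yw[:, int(np.argmax(np.var(Yw, axis=0)))].copy()
            if not np.any(u):
                u = Yw[:, 0] + 1e-12
            w_old = None
            for _ in range(self.max_iter):
                w = Xw.T @ u
                nrm = np.linalg.norm(w)
                if nrm == 0:
                    break
                w = _soft_threshold(w, budget[comp])
                nrm = np.linalg.norm(w)
                if nrm == 0:  # all weight shrunk away; keep the largest raw
                    w = Xw.T @ u
                    keep = int(np.argmax(np.abs(w)))
                    w = np.zeros(p)
                    w[keep] = 1.0
                    nrm = 1.0
                w = w / nrm
                t = Xw @ w
                tt = float(t @ t)
                if tt == 0:
                    break
                c = Yw.T @ t / tt
                u_new = Yw @ c / float(c @ c) if float(c @ c) else t
                if w_old is not None and np.linalg.norm(w - w_old) < self.tol:
                    u = u_new
                    break
                w_old = w
                u = u_new
            t = Xw @ w
            tt = float(t @ t)
            if tt == 0:
                h = comp
                break
            pl = Xw.T @ t / tt
            c = Yw.T @ t / tt
            Xw = Xw - np.outer(t, pl)
            Yw = Yw - np.outer(t, c)
            W[:, comp], Pl[:, comp], C[:, comp], T[:, comp] = w, pl, c, t

        W, Pl, C, T = W[:, :h], Pl[:, :h], C[:, :h], T[:, :h]
        self.n_components_ = h
        self.x_weights_ = W
        self.x_loadings_ = Pl
        self.y_loadings_ = C
        self.x_scores_ = T
        # regression coefficients on the working (scaled) X
        self.coef_ = W @ np.linalg.solve(Pl.T @ W, C.T)
        self.selected_features_ = [list(np.flatnonzero(np.abs(W[:, j]) > 0))
                                   for j in range(h)]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        Xw = (X - self._x_mean) / self._x_std
        return Xw @ self.coef_ + self._y_mean

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Xw = (X - self._x_mean) / self._x_std
        return Xw @ self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def plsda_fit(X, y, n_components: int = 3, **kw) -> PLSDAClassifier:
    """Dense PLS-DA (no feature budget)."""
    return PLSDAClassifier(n_components=n_components, keep_x=None, **kw).fit(X, y)


def splsda_fit(X, y, n_components: int = 3, keep_x=(5, 5, 5), **kw) -> PLSDAClassifier:
    """Sparse PLS-DA with a per-component feature budget (default 3 x 5)."""
    if keep_x == "all":
        keep_x = None
    return PLSDAClassifier(n_components=n_components, keep_x=keep_x, **kw).fit(X, y)


# ---------------------------------------------------------------------------
# ROC / AUROC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auroc: dict  # class -> one-vs-rest AUROC
    curves: dict = field(default_factory=dict)  # class -> (fpr, tpr, thresholds)
    priors: dict = field(default_factory=dict)
    cross_validated: bool = False


def _auc_mann_whitney(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUROC as the Mann–Whitney concordance of positive vs negative scores."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _roc_curve(scores: np.ndarray, positive: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positive[order].astype(float)
    tps = np.cumsum(pos)
    fps = np.cumsum(1.0 - pos)
    # one point per distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[distinct] / max(fps[-1], 1)]
    thr = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thr


def auroc_one_vs_rest(model: PLSDAClassifier, X, y, loo: bool = False) -> ROCResult:
    """Per-class one-vs-rest AUROC from the predicted class responses.

    With ``loo=True`` each sample is scored by a model refitted without it
    (leave-one-out cross-validation); the supplied fitted model provides
    the hyper-parameters.  Classes absent from ``y`` are skipped with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if loo:
        scores = np.zeros((X.shape[0], model.classes_.size))
        for i in range(X.shape[0]):
            keep = np.ones(X.shape[0], dtype=bool)
            keep[i] = False
            sub = clone(model).fit(X[keep], y[keep])
            row = np.full(model.classes_.size, -np.inf)
            dec = sub.decision_function(X[i : i + 1])[0]
            for j, cls in enumerate(sub.classes_):
                row[list(model.classes_).index(cls)] = dec[j]
            scores[i] = row
    else:
        scores = model.decision_function(X)

    result = ROCResult({}, {}, {}, cross_validated=loo)
    n = y.size
    for j, cls in enumerate(model.classes_):
        positive = y == cls
        if not positive.any():
            warnings.warn(f"class {cls!r} absent from y; skipped")
            continue
        result.auroc[cls] = _auc_mann_whitney(scores[:, j], positive)
        result.curves[cls] = _roc_curve(scores[:, j], positive)
        result.priors[cls] = float(positive.sum() / n)
    return result


def top_discriminating_features(model: PLSDAClassifier, feature_names=None,
                                per_component: int | None = None) -> list:
    """Features ranked by |loading| within component, components in order.

    Returns a list of (component, feature, weight) tuples with a stable
    ordering; each feature is reported at its first (strongest) appearance.
    """
    ranked = []
    seen = set()
    for j in range(model.n_components_):
        w = model.x_weights_[:, j]
        idx = [i for i in np.argsort(-np.abs(w), kind="stable") if w[i] != 0]
        if per_component is not None:
            idx = idx[:per_component]
        for i in idx:
            name = feature_names[i] if feature_names is not None else i
            if name in seen:
                continue
            seen.add(name)
            ranked.append((j + 1, name, float(w[i])))
    return ranked
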