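"""Supervised dimensionality reduction (OFNDA), LDA cross-validation,
accuracy summaries, window-size statistics and the timing harness.

OFNDA — orthogonal fuzzy neighbourhood discriminant analysis — replaces
the crisp class indicators of classical discriminant analysis with fuzzy
memberships derived from each instance's k nearest neighbours, builds
membership-weighted within/between scatter matrices, solves the
generalized eigenproblem and orthonormalises the retained directions.
The projection is capped at the number of classes.  The reduced features
feed a shared-covariance LDA evaluated with stratified 10-fold
cross-validation; accuracy distributions across window sizes are
compared with a Kruskal–Wallis test followed by Bonferroni-adjusted
pairwise rank tests.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .features_td import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OFNDAModel",
    "CVResult",
    "ofnda_fit",
    "ofnda_transform",
    "lda_crossval",
    "summarize_accuracy",
    "compare_window_sizes",
    "time_framework",
    "export_scatter",
]


@dataclass
class OFNDAModel:
    """Fitted OFNDA projection.

    ``projection`` is features × d with orthonormal columns (d at most
    the number of classes); ``mean`` is the training mean subtracted
    before projecting.
    """

    projection: np.ndarray
    mean: np.ndarray
    d: int
    class_set: list[object]


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold accuracies, one prediction per
    instance, and the pooled confusion matrix (rows = true class)."""

    fold_accuracies: np.ndarray
    predictions: np.ndarray
    confusion: np.ndarray
    class_set: list[object]

    @property
    def accuracy(self) -> float:
        """Overall fraction of correctly classified instances."""
        return float(np.trace(self.confusion) / np.sum(self.confusion))


def _fuzzy_memberships(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
                       k: int, eps: float = 1e-12) -> np.ndarray:
    """Instance-by-class membership matrix from inverse-distance-weighted
    k-nearest-neighbour votes, normalised per instance."""
    n = X.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    w = 1.0 / (dist + eps)
    U = np.zeros((n, n_classes))
    for i in range(n):
        np.add.at(U[i], y_idx[idx[i]], w[i])
    U /= U.sum(axis=1, keepdims=True)
    return U


def ofnda_fit(fm: FeatureMatrix, target_dim: int = 6, k_neighbors: int = 5,
              ridge: float = 1e-6) -> OFNDAModel:
    """Fit the OFNDA projection.

    Fuzzy memberships weight every instance's contribution to each class
    mean and to the within-class scatter; between-class scatter uses the
    membership mass per class.  Directions come from the generalized
    eigenproblem ``Sb v = λ (Sw + ridge·I) v`` and are Gram–Schmidt
    orthonormalised; the output dimension is capped at the number of
    classes (and at the feature count).
    """
    X = fm.values
    classes = sorted(set(fm.labels), key=lambda c: (str(type(c)), c))
    cls_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([cls_index[c] for c in fm.labels])
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx, minlength=n_classes)
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"every class needs at least k_neighbors+1={k_neighbors + 1} instances"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    p = Xc.shape[1]
    d = int(min(target_dim, n_classes, p))

    U = _fuzzy_memberships(Xc, y_idx, n_classes, k_neighbors)
    mass = U.sum(axis=0)                      # membership mass per class
    M = (U.T @ Xc) / mass[:, None]            # fuzzy class means
    Sw = np.zeros((p, p))
    for c in range(n_classes):
        D = Xc - M[c]
        Sw += (D * U[:, c:c + 1]).T @ D
    gm = (mass @ M) / mass.sum()
    Dm = M - gm
    Sb = (Dm * mass[:, None]).T @ Dm

    lam = ridge * (np.trace(Sw) / p + 1.0)
    Sw_r = Sw + lam * np.eye(p)
    if not np.all(np.isfinite(Sw)):
        raise ValueError("non-finite scatter matrix")
    try:
        evals, evecs = linalg.eigh(Sb, Sw_r)
    except linalg.LinAlgError:
        logger.warning("within-scatter ill-conditioned; increasing ridge")
        evals, evecs = linalg.eigh(Sb, Sw + (lam * 1e3) * np.eye(p))
    order = np.argsort(evals)[::-1][:d]
    V = evecs[:, order]
    # Gram-Schmidt (thin QR) orthonormalisation of the retained directions
    Q, _ = np.linalg.qr(V)
    return OFNDAModel(projection=Q, mean=mean, d=d, class_set=classes)


def ofnda_transform(model: OFNDAModel, fm: FeatureMatrix) -> FeatureMatrix:
    """Project a feature matrix onto the fitted OFNDA directions."""
    if fm.values.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"feature count {fm.values.shape[1]} does not match the model "
            f"({model.projection.shape[0]})"
        )
    Z = (fm.values - model.mean) @ model.projection
    names = [f"ofnda.dim{j + 1}" for j in range(model.d)]
    return FeatureMatrix(values=Z, labels=list(fm.labels), names=names)


def lda_crossval(fm: FeatureMatrix, folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validated LDA.

    Folds come from a seeded stratified shuffle; a shared-covariance LDA
    (SVD solver) is fit on k−1 folds and predicts the held-out fold, so
    every instance is predicted exactly once.  Fold accuracy is the
    fraction of correctly classified instances.
    """
    X = fm.values
    classes = sorted(set(fm.labels), key=lambda c: (str(type(c)), c))
    y = np.array([classes.index(c) for c in fm.labels])
    counts = np.bincount(y, minlength=len(classes))
    if counts.min() < folds:
        short = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {short!r} has {counts.min()} instances; "
            f"{folds}-fold stratified CV needs at least {folds} per class"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    fold_acc = np.empty(folds)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X[tr], y[tr])
        p = clf.predict(X[te])
        preds[te] = p
        fold_acc[f] = float(np.mean(p == y[te]))
    conf = _sk_confusion(y, preds, labels=np.arange(len(classes)))
    return CVResult(fold_accuracies=fold_acc, predictions=preds,
                    confusion=conf, class_set=classes)


def summarize_accuracy(values: np.ndarray) -> dict:
    """Box statistics: median, quartiles, 1.5·IQR whiskers and outliers.

    Quartiles use linear interpolation.  Whiskers sit at the most
    extreme data points within 1.5 times the interquartile range of the
    box; points beyond are reported as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarise")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
    }


def compare_window_sizes(groups: dict[object, np.ndarray], alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Kruskal–Wallis across groups plus Bonferroni-adjusted pairwise tests.

    ``groups`` maps a group key (e.g. window size in ms) to its accuracy
    values.  Returns a table with one row per pair: the pairwise
    rank-sum p-value, its Bonferroni-adjusted value (multiplied by the
    number of pairs, clipped at 1) and a significance flag at ``alpha``.
    The overall H-test result is attached as ``df.attrs``.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p_kw = 0.0, 1.0  # identical values everywhere: no evidence
    else:
        h, p_kw = stats.kruskal(*arrays)
    rows = []
    pairs = [(i, j) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    m = len(pairs)
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({
            "group_a": keys[i],
            "group_b": keys[j],
            "p_raw": float(p),
            "p_bonferroni": float(min(1.0, p * m)),
            "significant": bool(min(1.0, p * m) < alpha),
        })
    df = pd.DataFrame(rows)
    df.attrs["kruskal_h"] = float(h)
    df.attrs["kruskal_p"] = float(p_kw)
    df.attrs["alpha"] = alpha
    return df


def _single_window_extractor(framework: str):
    """Return f(block) computing one window's feature vector (first
    iteration of the fusion recursion, i.e. the pointwise-switch path)."""
    from . import features_td as ft
    from . import stw as stw_mod

    if framework == "mav":
        return lambda b: ft.window_fusion(np.mean(np.abs(b), axis=1), None)
    if framework == "mav_wl":
        return lambda b: ft.window_fusion(np.concatenate([
            np.mean(np.abs(b), axis=1),
            np.sum(np.abs(np.diff(b, axis=1)), axis=1)]), None)
    if framework == "tdd":
        cfg = ft.TDDConfig()
        return lambda b: ft._tdd_similarity_block(b, cfg).ravel()
    if framework == "tsd":
        cfg = ft.TDDConfig()

        def tsd_one(b):
            X = ft._stream_matrix(b)
            Xn = ft.nonlinear_version(X, cfg.eps)
            a = np.hstack([ft._tdd_matrix(X, cfg), ft._tsd_extra_matrix(X, cfg.eps)])
            c = np.hstack([ft._tdd_matrix(Xn, cfg), ft._tsd_extra_matrix(Xn, cfg.eps)])
            return np.vstack([ft.tsd_similarity(a[s], c[s]) for s in range(a.shape[0])]).ravel()

        return tsd_one
    if framework == "stw":
        cfg = stw_mod.STWConfig()

        def stw_one(b):
            state = stw_mod.STWState.initial(stw_mod.stw_feature_count(b.shape[0]))
            out, _ = stw_mod.stw_step(stw_mod.stw_raw_vector(b, cfg), state, cfg)
            return out

        return stw_one
    raise ValueError(f"unknown framework {framework!r}")


def time_framework(framework: str, window_ms: float, n_channels: int,
                   fs: float, repeats: int = 1000, seed: int = 0) -> float:
    """Mean wall-clock seconds to extract one window's features.

    A fixed seeded Gaussian window of ``n_channels × round(window_ms/1000
    · fs)`` samples is extracted ``repeats`` times after one untimed
    warm-up call (which also absorbs JIT compilation).  Pure observation:
    feature outputs are unaffected.
    """
    rng = np.random.default_rng(seed)
    W = int(round(window_ms / 1000.0 * fs))
    block = rng.standard_normal((n_channels, W))
    fn = _single_window_extractor(framework)
    fn(block)  # warm-up
    t0 = time.perf_counter()
    for _ in range(repeats):
        fn(block)
    return (time.perf_counter() - t0) / repeats


def export_scatter(fm_reduced: FeatureMatrix, path) -> None:
    """Write the first two reduced dimensions plus labels as CSV."""
    if fm_reduced.n_features < 2:
        raise ValueError("need at least 2 reduced dimensions to scatter")
    df = pd.DataFrame({
        "dim1": fm_reduced.values[:, 0],
        "dim2": fm_reduced.values[:, 1],
        "label": fm_reduced.labels,
    })
    df.to_csv(path, index=False)
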