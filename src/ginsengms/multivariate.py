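"""Normalization and the classical chemometric baselines (PCA, PLS-DA).

Two column-wise normalizations of the peak-area matrix:

* *mean normalization* divides each feature by its across-sample mean,
  so every feature column averages 1;
* *Z-score normalization* centers and scales each feature to mean 0
  and unit standard deviation (population denominator), putting all
  features on a common scale regardless of their raw intensity.

PCA diagonalizes the sample covariance of the centered matrix;
PLS-DA decomposes X = T P' + E and the one-hot class matrix
Y = U Q' + F with latent components chosen to maximize the covariance
between the X- and Y-scores (NIPALS), reporting R2Y (fit) and Q2
(cross-validated predictive ability) plus a label-permutation test
whose regression intercepts at zero label correlation diagnose
overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ginsengms.features import FeatureTable
from ginsengms.validation import stratified_kfold

__all__ = [
    "NormalizedTable",
    "PcaResult",
    "PlsdaResult",
    "PermutationTestResult",
    "normalize_mean",
    "normalize_zscore",
    "fit_pca",
    "fit_plsda",
    "permutation_test_plsda",
]


def _as_matrix(ft: "FeatureTable | np.ndarray") -> tuple[np.ndarray, list[str]]:
    if isinstance(ft, FeatureTable):
        return ft.areas.astype(float), list(ft.feature_ids)
    X = np.asarray(ft, dtype=float)
    return X, [f"F{j + 1:04d}" for j in range(X.shape[1])]


@dataclass
class NormalizedTable:
    """A normalized matrix plus the statistics needed to reuse the map.

    ``means``/``sds`` are the per-feature training statistics;
    :meth:`apply` transforms new data (e.g. external test samples)
    with these stored statistics rather than re-estimating them.
    """

    values: np.ndarray
    method: str  # "mean" | "zscore" | "none"
    means: np.ndarray
    sds: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Transform new rows with the stored training statistics."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.means):
            raise ValueError(
                f"expected {len(self.means)} features, got {X.shape[1]}"
            )
        if self.method == "mean":
            return X / self.means
        if self.method == "zscore":
            return (X - self.means) / self.sds
        return X.copy()


def normalize_mean(ft: "FeatureTable | np.ndarray") -> NormalizedTable:
    """Divide every feature column by its mean across samples."""
    X, ids = _as_matrix(ft)
    means = X.mean(axis=0)
    bad = np.nonzero(means == 0)[0]
    if bad.size:
        raise ValueError(
            f"mean normalization undefined for zero-mean feature(s) "
            f"{[ids[j] for j in bad[:5]]}"
        )
    return NormalizedTable(values=X / means, method="mean", means=means, feature_ids=ids)


def normalize_zscore(ft: "FeatureTable | np.ndarray", ddof: int = 0) -> NormalizedTable:
    """Center and scale every feature column to mean 0, sd 1.

    The population standard deviation (``ddof=0``) is the default: the
    intent of the transform is that each feature follows a standard
    normal scale.  Set ``ddof=1`` for the sample-sd variant.
    """
    X, ids = _as_matrix(ft)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    bad = np.nonzero(sds == 0)[0]
    if bad.size:
        raise ValueError(
            f"Z-score undefined for zero-variance feature(s) "
            f"{[ids[j] for j in bad[:5]]}"
        )
    return NormalizedTable(
        values=(X - means) / sds, method="zscore", means=means, sds=sds, feature_ids=ids
    )


@dataclass
class PcaResult:
    """Loadings (orthonormal columns), scores, and variance ratios."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def fit_pca(X: np.ndarray, n_components: int) -> PcaResult:
    """Principal components via eigendecomposition of the sample covariance.

    Columns of ``X`` are centered; components are ordered by
    descending eigenvalue with a deterministic sign convention (the
    largest-magnitude loading entry of each component is positive).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not (1 <= n_components <= min(n - 1, m)):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, m)}], got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    loadings = eigvecs[:, :n_components]
    # sign convention: largest-|entry| loading element positive
    for c in range(loadings.shape[1]):
        jmax = np.argmax(np.abs(loadings[:, c]))
        if loadings[jmax, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = Xc @ loadings
    ratio = eigvals[:n_components] / total if total > 0 else np.zeros(n_components)
    return PcaResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=ratio,
        mean=mean,
    )


def _one_hot(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


@dataclass
class PlsdaResult:
    """NIPALS PLS-DA decomposition and its fit/prediction diagnostics.

    ``x_scores`` (T), ``y_scores`` (U), ``x_loadings`` (P),
    ``y_loadings`` (Q) and ``weights`` (W) satisfy
    ``X_centered = T P' + E`` and ``Y_centered = T Q' + F`` after
    fitting; ``r2y`` is the fraction of Y variance explained and
    ``q2`` its cross-validated counterpart.
    """

    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    weights: np.ndarray
    x_residual: np.ndarray
    y_residual: np.ndarray
    n_components: int
    r2y: float
    q2: float
    classes: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predicted (centered-Y scale) class responses for new rows."""
        return (np.asarray(X, float) - self.x_mean) @ self.coef

    def predict(self, X: np.ndarray) -> list[str]:
        """Hard class assignment: the column with the largest response."""
        yhat = self.predict_scores(X) + self.y_mean
        return [self.classes[i] for i in np.argmax(yhat, axis=1)]


def _nipals_pls2(
    X: np.ndarray, Y: np.ndarray, n_components: int, max_iter: int = 500, tol: float = 1e-10
):
    """NIPALS PLS2: iterative extraction of covariance-maximizing scores."""
    Xd, Yd = X.copy(), Y.copy()
    n, m = X.shape
    q = Y.shape[1]
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros((q, n_components))
    W = np.zeros((m, n_components))
    for a in range(n_components):
        u = Yd[:, np.argmax(np.sum(Yd**2, axis=0))].copy()
        t = None
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            wn = np.linalg.norm(w)
            if wn == 0:
                break
            w /= wn
            t = Xd @ w
            qv = Yd.T @ t / (t @ t)
            qn = np.linalg.norm(qv)
            if qn == 0:
                break
            u = Yd @ qv / (qv @ qv)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = 0.0 if t is None else t @ t
        if tt == 0:
            T, U, P, Q, W = (M[:, :a] for M in (T, U, P, Q, W))
            break
        p = Xd.T @ t / tt
        qv = Yd.T @ t / tt
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, qv)
        T[:, a], U[:, a], P[:, a], Q[:, a], W[:, a] = t, u, p, qv, w
    return T, U, P, Q, W, Xd, Yd


def fit_plsda(
    X: np.ndarray,
    labels: Sequence[str],
    n_components: int | None = None,
    q2_folds: int = 10,
    seed: int = 0,
) -> PlsdaResult:
    """Fit PLS-DA on ``X`` against one-hot class labels.

    ``n_components`` defaults to (number of classes - 1).  ``r2y`` is
    1 - ||F||^2/||Y_centered||^2; ``q2`` is 1 - PRESS/SS from seeded
    stratified ``q2_folds``-fold cross-validation, with PRESS the
    prediction error sum of squares on held-out rows.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels must align with rows of X")
    Y, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA requires at least two classes")
    if n_components is None:
        n_components = len(classes) - 1
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    T, U, P, Q, W, E, F = _nipals_pls2(Xc, Yc, n_components)
    ss_y = float(np.sum(Yc**2))
    r2y = 1.0 - float(np.sum(F**2)) / ss_y
    coef = _pls_coef(W, P, Q)

    # Q2 by stratified CV: refit on each training split, accumulate PRESS
    press = 0.0
    folds = stratified_kfold(labels, k=min(q2_folds, X.shape[0]), seed=seed)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        xm = X[train_idx].mean(axis=0)
        ym = Y[train_idx].mean(axis=0)
        a = min(n_components, np.linalg.matrix_rank(X[train_idx] - xm))
        Tt, Ut, Pt, Qt, Wt, _, _ = _nipals_pls2(X[train_idx] - xm, Y[train_idx] - ym, a)
        Bt = _pls_coef(Wt, Pt, Qt)
        yhat = (X[test_idx] - xm) @ Bt + ym
        press += float(np.sum((Y[test_idx] - yhat) ** 2))
    q2 = 1.0 - press / ss_y

    return PlsdaResult(
        x_scores=T,
        y_scores=U,
        x_loadings=P,
        y_loadings=Q,
        weights=W,
        x_residual=E,
        y_residual=F,
        n_components=T.shape[1],
        r2y=r2y,
        q2=q2,
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
    )


def _pls_coef(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Regression coefficients B with Yhat_centered = X_centered @ B."""
    if W.shape[1] == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    return W @ np.linalg.solve(P.T @ W, Q.T)


@dataclass
class PermutationTestResult:
    """Label-permutation diagnostics of a PLS-DA model.

    Each row of ``records`` is (correlation between permuted and
    original one-hot labels, R2Y, Q2); the unpermuted model enters at
    correlation 1.  Intercepts are the values at correlation 0 of the
    least-squares lines through all points.
    """

    records: np.ndarray  # (n_perm + 1, 3): correlation, r2y, q2
    r2_intercept: float
    q2_intercept: float
    observed_r2y: float
    observed_q2: float
    seed: int


def permutation_test_plsda(
    X: np.ndarray,
    labels: Sequence[str],
    n_perm: int = 100,
    seed: int = 0,
    n_components: int | None = None,
    q2_folds: int = 10,
) -> PermutationTestResult:
    """Permutation test of PLS-DA class separation.

    For each of ``n_perm`` shuffles of the labels the model is refit
    and (label correlation, R2Y, Q2) recorded; a genuine class
    structure shows the unpermuted R2Y/Q2 well above the permuted
    cloud and regression intercepts near or below zero.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a meaningful intercept")
    labels = list(labels)
    base = fit_plsda(X, labels, n_components=n_components, q2_folds=q2_folds, seed=seed)
    Y0, _ = _one_hot(labels)
    Y0c = (Y0 - Y0.mean(axis=0)).ravel()
    rng = np.random.default_rng(seed)
    rows = [(1.0, base.r2y, base.q2)]
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        plabels = [labels[i] for i in perm]
        res = fit_plsda(X, plabels, n_components=n_components, q2_folds=q2_folds, seed=seed)
        Yp, _ = _one_hot(plabels)
        Ypc = (Yp - Yp.mean(axis=0)).ravel()
        denom = np.linalg.norm(Y0c) * np.linalg.norm(Ypc)
        corr = abs(float(Y0c @ Ypc / denom)) if denom > 0 else 0.0
        rows.append((corr, res.r2y, res.q2))
    records = np.array(rows)
    r2_int = _intercept(records[:, 0], records[:, 1])
    q2_int = _intercept(records[:, 0], records[:, 2])
    return PermutationTestResult(
        records=records,
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        observed_r2y=base.r2y,
        observed_q2=base.q2,
        seed=seed,
    )


def _intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)
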