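"""Soft-margin kernel SVM solved in its dual form.

The binary C-SVM dual

    maximize   sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    subject to 0 <= a_i <= C,  sum_i a_i y_i = 0

is solved by sequential minimal optimization with most-violating-pair
working-set selection: at each step the pair of coefficients with the
largest Karush-Kuhn-Tucker violation is updated analytically under the
box and equality constraints, until the maximal violation falls below
a tolerance.  The bias ``b`` is recovered from the free support
vectors (0 < a < C), which sit exactly on the margin, y f(x) = 1.

The decision function is the kernel expansion
``f(x) = sum_i a_i y_i K(x_i, x) + b``; the primal weight vector
``w = sum_i a_i y_i x_i`` is only materialized for the linear kernel
(for the RBF kernel it lives implicitly in feature space).

Multi-class problems are handled one-vs-one with majority voting;
hyperparameters (C, gamma) are chosen on a log2 grid by seeded
stratified ten-fold cross-validation, preferring smaller C then
smaller gamma on ties (the accuracy surface typically shows a large
plateau, so the choice favors stronger regularization).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ginsengms.validation import stratified_kfold

__all__ = [
    "SvmModel",
    "MulticlassSvmModel",
    "GridSearchResult",
    "ConvergenceError",
    "kernel_eval",
    "kernel_matrix",
    "fit_binary_svm",
    "fit_multiclass_svm",
    "cross_validate",
    "grid_search",
    "dual_objective",
]

DEFAULT_C = 1.0
DEFAULT_GAMMA = 0.03


class ConvergenceError(RuntimeError):
    pass


def kernel_eval(
    x: np.ndarray, z: np.ndarray, kernel: str = "rbf", gamma: float = DEFAULT_GAMMA
) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if kernel == "linear":
        return float(x @ z)
    if kernel == "rbf":
        if gamma <= 0:
            raise ValueError("gamma must be positive for the RBF kernel")
        d = x - z
        return float(np.exp(-gamma * (d @ d)))
    raise ValueError(f"unknown kernel {kernel!r}")


def kernel_matrix(
    X: np.ndarray, Z: np.ndarray, kernel: str = "rbf", gamma: float = DEFAULT_GAMMA
) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if kernel == "linear":
        return X @ Z.T
    if kernel == "rbf":
        if gamma <= 0:
            raise ValueError("gamma must be positive for the RBF kernel")
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Z**2, axis=1)[None, :]
            - 2.0 * (X @ Z.T)
        )
        return np.exp(-gamma * np.clip(sq, 0.0, None))
    raise ValueError(f"unknown kernel {kernel!r}")


def _smo_core_py(
    K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Reference NumPy implementation of the SMO iteration.

    Returns (alpha, gradient G = Qa - e, status) with status 0 on
    convergence, 1 when ``max_iter`` was exhausted.
    """
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    G = -np.ones(n)
    status = 1
    for _ in range(max_iter):
        up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < C - 1e-12))
        if not up.any() or not low.any():
            status = 0
            break
        yG = -y * G
        i = np.nonzero(up)[0][np.argmax(yG[up])]
        j = np.nonzero(low)[0][np.argmin(yG[low])]
        if yG[i] - yG[j] < tol:
            status = 0
            break
        # analytic update of the pair (i, j)
        quad = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        quad = max(quad, 1e-12)
        delta = (yG[i] - yG[j]) / quad
        # move along the equality-constraint direction, clipped to the box
        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] > 0:
            hi_i = C - ai_old
            lo_i = -ai_old
        else:
            hi_i = ai_old
            lo_i = ai_old - C
        if y[j] > 0:
            hi_j = aj_old
            lo_j = aj_old - C
        else:
            hi_j = C - aj_old
            lo_j = -aj_old
        step = min(delta, hi_i, hi_j)
        step = max(step, lo_i, lo_j)
        if step == 0.0:
            status = 0
            break
        dai = y[i] * step
        daj = -y[j] * step
        alpha[i] = ai_old + dai
        alpha[j] = aj_old + daj
        G += Q[:, i] * dai + Q[:, j] * daj
    return alpha, G, status


def _build_smo_core_nb():
    """Compiled twin of :func:`_smo_core_py` (identical iterate-for-iterate)."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=True, fastmath=False)
    def _smo_core_nb(K, y, C, tol, max_iter):  # pragma: no cover - compiled
        n = K.shape[0]
        alpha = np.zeros(n)
        G = -np.ones(n)
        status = 1
        for _ in range(max_iter):
            gmax = -1e300
            gmin = 1e300
            i = -1
            j = -1
            for t in range(n):
                yg = -y[t] * G[t]
                if (y[t] > 0 and alpha[t] < C - 1e-12) or (
                    y[t] < 0 and alpha[t] > 1e-12
                ):
                    if yg > gmax:
                        gmax = yg
                        i = t
                if (y[t] > 0 and alpha[t] > 1e-12) or (
                    y[t] < 0 and alpha[t] < C - 1e-12
                ):
                    if yg < gmin:
                        gmin = yg
                        j = t
            if i < 0 or j < 0:
                status = 0
                break
            if gmax - gmin < tol:
                status = 0
                break
            quad = (
                y[i] * y[i] * K[i, i]
                + y[j] * y[j] * K[j, j]
                - 2.0 * y[i] * y[j] * (y[i] * y[j] * K[i, j])
            )
            if quad < 1e-12:
                quad = 1e-12
            delta = (gmax - gmin) / quad
            ai_old = alpha[i]
            aj_old = alpha[j]
            if y[i] > 0:
                hi_i = C - ai_old
                lo_i = -ai_old
            else:
                hi_i = ai_old
                lo_i = ai_old - C
            if y[j] > 0:
                hi_j = aj_old
                lo_j = aj_old - C
            else:
                hi_j = C - aj_old
                lo_j = -aj_old
            step = delta
            if hi_i < step:
                step = hi_i
            if hi_j < step:
                step = hi_j
            if lo_i > step:
                step = lo_i
            if lo_j > step:
                step = lo_j
            if step == 0.0:
                status = 0
                break
            dai = y[i] * step
            daj = -y[j] * step
            alpha[i] = ai_old + dai
            alpha[j] = aj_old + daj
            for t in range(n):
                G[t] += (y[t] * y[i] * K[t, i]) * dai + (y[t] * y[j] * K[t, j]) * daj
            status = 1
        return alpha, G, status

    return _smo_core_nb


_smo_core_nb = _build_smo_core_nb()


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float]:
    """Most-violating-pair SMO on a precomputed Gram matrix.

    Minimizes 0.5 a'Qa - e'a with Q = (y y') * K over the feasible
    box.  ``G`` tracks the gradient Qa - e.  Selection and the
    stopping rule follow the standard maximal-violating-pair scheme;
    ``tol`` bounds the final KKT violation.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if _smo_core_nb is not None:
        alpha, G, status = _smo_core_nb(K, y, float(C), float(tol), int(max_iter))
    else:
        alpha, G, status = _smo_core_py(K, y, float(C), float(tol), int(max_iter))
    if status != 0:
        raise ConvergenceError(
            f"SMO did not reach tolerance {tol} within {max_iter} iterations"
        )

    # bias from the free support vectors (on-margin points); fall back to
    # the midpoint of the KKT-feasible interval when none are free
    yG = -y * G
    free = (alpha > 1e-8 * C) & (alpha < C * (1 - 1e-8))
    if free.any():
        b = float(np.mean(yG[free]))
    else:
        up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < C - 1e-12))
        hi = yG[up].max() if up.any() else 0.0
        lo = yG[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b


@dataclass
class SvmModel:
    """A fitted binary SVM in dual form.

    Only vectors with a nonzero dual coefficient are stored; the
    decision function is f(x) = sum_i alpha_i y_i K(sv_i, x) + b.
    """

    support_vectors: np.ndarray
    alphas: np.ndarray
    sv_labels: np.ndarray  # in {-1, +1}
    b: float
    kernel: str
    gamma: float
    C: float
    dual_objective_value: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        K = kernel_matrix(self.support_vectors, X, self.kernel, self.gamma)
        return (self.alphas * self.sv_labels) @ K + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    @property
    def w(self) -> np.ndarray:
        """Primal weight vector; defined only for the linear kernel."""
        if self.kernel != "linear":
            raise ValueError(
                "the primal weight vector is only materialized for the linear "
                "kernel; RBF models use the kernel expansion"
            )
        return (self.alphas * self.sv_labels) @ self.support_vectors

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kernel": self.kernel,
            "gamma": self.gamma,
            "C": self.C,
            "b": self.b,
            "alphas": self.alphas.tolist(),
            "sv_labels": self.sv_labels.tolist(),
            "support_vectors": self.support_vectors.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def dual_objective(
    alpha: np.ndarray, K: np.ndarray, y: np.ndarray
) -> float:
    """Value of the dual objective sum(a) - 1/2 a'(yy'*K)a."""
    alpha = np.asarray(alpha, float)
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def fit_binary_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    kernel: str = "rbf",
    gamma: float = DEFAULT_GAMMA,
    tol: float = 1e-4,
    max_iter: int = 100_000,
) -> SvmModel:
    """Fit a two-class SVM with labels in {-1, +1} by SMO."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("y must contain both labels -1 and +1")
    if C <= 0:
        raise ValueError("C must be positive")
    K = kernel_matrix(X, X, kernel, gamma)
    alpha, b = _smo(K, y, C, tol, max_iter)
    keep = alpha > 1e-12
    obj = dual_objective(alpha, K, y)
    return SvmModel(
        support_vectors=X[keep].copy(),
        alphas=alpha[keep].copy(),
        sv_labels=y[keep].copy(),
        b=b,
        kernel=kernel,
        gamma=gamma,
        C=C,
        dual_objective_value=obj,
    )


@dataclass
class MulticlassSvmModel:
    """One-vs-one combination of binary SVMs with majority voting.

    Ties are broken by the summed decision values of the involved
    binary machines, then by class order.
    """

    classes: list[str]
    machines: list[tuple[str, str, SvmModel]]
    kernel: str = "rbf"
    gamma: float = DEFAULT_GAMMA
    C: float = DEFAULT_C

    def predict(self, X: np.ndarray) -> list[str]:
        X = np.atleast_2d(np.asarray(X, float))
        n = X.shape[0]
        votes = np.zeros((n, len(self.classes)))
        scores = np.zeros((n, len(self.classes)))
        cidx = {c: k for k, c in enumerate(self.classes)}
        for ca, cb, m in self.machines:
            f = m.decision_function(X)
            # +1 side of the binary machine is class ca
            votes[:, cidx[ca]] += f >= 0
            votes[:, cidx[cb]] += f < 0
            scores[:, cidx[ca]] += f
            scores[:, cidx[cb]] -= f
        out = []
        for i in range(n):
            best = max(
                range(len(self.classes)),
                key=lambda k: (votes[i, k], scores[i, k], -k),
            )
            out.append(self.classes[best])
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": self.classes,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "C": self.C,
            "machines": [
                {"positive": ca, "negative": cb, "model": json.loads(m.to_json())}
                for ca, cb, m in self.machines
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_multiclass_svm(
    X: np.ndarray,
    labels: Sequence[str],
    C: float = DEFAULT_C,
    kernel: str = "rbf",
    gamma: float = DEFAULT_GAMMA,
    tol: float = 1e-4,
) -> MulticlassSvmModel:
    """One-vs-one multi-class SVM over string class labels."""
    X = np.atleast_2d(np.asarray(X, float))
    labels = np.asarray([str(l) for l in labels])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("at least two classes required")
    machines = []
    for ca, cb in itertools.combinations(classes, 2):
        mask = (labels == ca) | (labels == cb)
        y = np.where(labels[mask] == ca, 1.0, -1.0)
        machines.append(
            (ca, cb, fit_binary_svm(X[mask], y, C=C, kernel=kernel, gamma=gamma, tol=tol))
        )
    return MulticlassSvmModel(
        classes=classes, machines=machines, kernel=kernel, gamma=gamma, C=C
    )


def _ovo_predict_gram(
    K: np.ndarray,
    labels: np.ndarray,
    classes: list[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    C: float,
    tol: float = 1e-4,
    max_iter: int = 100_000,
) -> list[str]:
    """One-vs-one prediction of ``test_idx`` rows from a full Gram matrix.

    Mirrors ``fit_multiclass_svm`` + ``MulticlassSvmModel.predict``
    exactly (same SMO, same vote and tie rules) but never rebuilds
    kernel entries, which makes repeated evaluation cheap.
    """
    votes = np.zeros((len(test_idx), len(classes)))
    scores = np.zeros((len(test_idx), len(classes)))
    cidx = {c: kk for kk, c in enumerate(classes)}
    for ca, cb in itertools.combinations(classes, 2):
        mask = (labels[train_idx] == ca) | (labels[train_idx] == cb)
        sub = train_idx[mask]
        y = np.where(labels[sub] == ca, 1.0, -1.0)
        alpha, b = _smo(K[np.ix_(sub, sub)], y, C, tol, max_iter)
        keep = alpha > 1e-12
        f = (alpha[keep] * y[keep]) @ K[np.ix_(sub[keep], test_idx)] + b
        votes[:, cidx[ca]] += f >= 0
        votes[:, cidx[cb]] += f < 0
        scores[:, cidx[ca]] += f
        scores[:, cidx[cb]] -= f
    out = []
    for i in range(len(test_idx)):
        best = max(
            range(len(classes)), key=lambda kk: (votes[i, kk], scores[i, kk], -kk)
        )
        out.append(classes[best])
    return out


def _oof_predictions_gram(
    K: np.ndarray,
    labels: np.ndarray,
    classes: list[str],
    folds: list[np.ndarray],
    C: float,
) -> list[str]:
    n = K.shape[0]
    preds: list[str] = [""] * n
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        for i, p in zip(
            test_idx, _ovo_predict_gram(K, labels, classes, train_idx, test_idx, C)
        ):
            preds[i] = p
    return preds


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    k: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
) -> tuple[float, list[str]]:
    """Seeded stratified k-fold cross-validation accuracy.

    Every sample is predicted by a model that never saw it; returns
    (accuracy = correct / n, per-sample out-of-fold predictions).
    The full Gram matrix is computed once and sliced per fold.
    """
    X = np.atleast_2d(np.asarray(X, float))
    labels_arr = np.asarray([str(l) for l in labels])
    n = X.shape[0]
    folds = stratified_kfold(labels_arr, k=k, seed=seed)
    classes = sorted(set(labels_arr))
    if len(classes) < 2:
        raise ValueError("at least two classes required")
    K = kernel_matrix(X, X, kernel, gamma)
    preds = _oof_predictions_gram(K, labels_arr, classes, folds, C)
    acc = sum(p == t for p, t in zip(preds, labels_arr)) / n
    return float(acc), list(preds)


@dataclass
class GridSearchResult:
    """Cross-validated accuracy surface over the (C, gamma) grid."""

    C_grid: np.ndarray
    gamma_grid: np.ndarray
    accuracy: np.ndarray  # shape (len(C_grid), len(gamma_grid))
    best_C: float
    best_gamma: float
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        rows = [
            (float(c), float(g), float(self.accuracy[i, j]))
            for i, c in enumerate(self.C_grid)
            for j, g in enumerate(self.gamma_grid)
        ]
        return pd.DataFrame(rows, columns=["C", "gamma", "accuracy"])


def default_grids() -> tuple[np.ndarray, np.ndarray]:
    """Log2 grids: C in 2^-5..2^15, gamma in 2^-15..2^3, steps of 2^2."""
    return (
        2.0 ** np.arange(-5, 16, 2, dtype=float),
        2.0 ** np.arange(-15, 4, 2, dtype=float),
    )


def grid_search(
    X: np.ndarray,
    labels: Sequence[str],
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    k: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
) -> GridSearchResult:
    """Exhaustive (C, gamma) search by stratified k-fold CV accuracy.

    The chosen cell attains the maximal accuracy; ties break toward
    the smallest C, then the smallest gamma (prefer the most
    regularized model on the accuracy plateau).
    """
    if C_grid is None or gamma_grid is None:
        dC, dg = default_grids()
        C_grid = dC if C_grid is None else np.asarray(C_grid, float)
        gamma_grid = dg if gamma_grid is None else np.asarray(gamma_grid, float)
    C_grid = np.asarray(sorted(C_grid), float)
    gamma_grid = np.asarray(sorted(gamma_grid), float)
    if C_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("grids must be nonempty")
    acc = np.zeros((C_grid.size, gamma_grid.size))
    for i, C in enumerate(C_grid):
        for j, g in enumerate(gamma_grid):
            acc[i, j], _ = cross_validate(
                X, labels, C=C, gamma=g, k=k, seed=seed, kernel=kernel
            )
    best = np.unravel_index(
        np.argmax(np.round(acc, 12)), acc.shape
    )
    # resolve ties explicitly toward small C then small gamma
    best_val = acc[best]
    for i in range(C_grid.size):
        done = False
        for j in range(gamma_grid.size):
            if acc[i, j] >= best_val - 1e-12:
                best = (i, j)
                done = True
                break
        if done:
            break
    return GridSearchResult(
        C_grid=C_grid,
        gamma_grid=gamma_grid,
        accuracy=acc,
        best_C=float(C_grid[best[0]]),
        best_gamma=float(gamma_grid[best[1]]),
        seed=seed,
    )
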