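"""Latent-variable models for two-group discrimination.

PCA (via SVD), PLS-DA (NIPALS PLS1 on a centered 0/1 class vector),
OPLS-DA (orthogonal signal correction followed by one predictive
component), stratified k-fold cross-validated Q2 = 1 - PRESS/TSS, and a
label-permutation test whose empirical p uses the add-one rule
(count(null >= observed) + 1) / (n_perm + 1) — so with 1000 permutations
the smallest attainable p is 1/1001, the conventional "< 0.001" floor.

The class vector is dummy-coded {0, 1} and centered; a sample is assigned
to class 1 when its predicted score exceeds 0.5 on the 0/1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LatentModel",
    "PermutationTestResult",
    "pca",
    "plsda",
    "oplsda",
    "cross_validate_q2",
    "permutation_test",
    "encode_labels",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class LatentModel:
    method: str
    scores: np.ndarray                 # samples x components
    loadings: np.ndarray               # features x components
    weights: np.ndarray | None = None  # PLS x-weights
    y_loadings: np.ndarray | None = None
    orthogonal_scores: np.ndarray | None = None
    orthogonal_loadings: np.ndarray | None = None
    R2X: float = 0.0
    R2Y: float | None = None
    Q2: float | None = None
    n_components: int = 0
    explained_variance_ratio: np.ndarray | None = None


@dataclass
class PermutationTestResult:
    statistic: str
    observed: float
    null_values: np.ndarray
    empirical_p: float


def encode_labels(y) -> np.ndarray:
    """Dummy-code a two-level label vector as {0, 1} in sorted label order.

    Sorting ties the coding to label identity, not sample order, so swapping
    the two groups flips the centered class vector's sign (and with it the
    predictive score signs) instead of silently re-encoding.
    """
    y = np.asarray(y)
    levels = sorted(set(y.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 classes, found {len(levels)}: {levels}")
    return np.array([levels.index(v) for v in y], dtype=float)


def pca(X, n_components: int = 2) -> LatentModel:
    """Principal component analysis of a centered matrix via SVD."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    total = (S**2).sum()
    evr = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return LatentModel(
        method="pca",
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        R2X=float(evr.sum()),
        n_components=k,
        explained_variance_ratio=evr,
    )


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1. Returns (T, P, W, q, R2Y). X and y must be centered."""
    Xd = X.copy()
    yd = y.copy()
    n, p = X.shape
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    W = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < _NIPALS_TOL:
            # no covariance left; truncate
            T, P, W, q = T[:, :a], P[:, :a], W[:, :a], q[:a]
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < _NIPALS_TOL:
            T, P, W, q = T[:, :a], P[:, :a], W[:, :a], q[:a]
            break
        pvec = Xd.T @ t / tt
        qa = (yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        T[:, a], P[:, a], W[:, a], q[a] = t, pvec, w, qa
    y_hat = T @ q
    ss_tot = float(y @ y)
    r2y = 1.0 - float((y - y_hat) @ (y - y_hat)) / ss_tot if ss_tot > 0 else 0.0
    return T, P, W, q, r2y


def plsda(X, y, n_components: int = 2) -> LatentModel:
    """PLS discriminant analysis on an autoscaled matrix and two-level labels."""
    X = np.asarray(X, dtype=float)
    y01 = encode_labels(y)
    yc = y01 - y01.mean()
    T, P, W, q, r2y = _nipals_pls1(X, yc, n_components)
    ssx = float((X**2).sum())
    r2x = float((T**2 * (P**2).sum(axis=0)).sum() / ssx) if ssx > 0 else 0.0
    return LatentModel(
        method="plsda", scores=T, loadings=P, weights=W, y_loadings=q,
        R2X=r2x, R2Y=r2y, n_components=T.shape[1],
    )


def _pls1_predict(X_new, x_mean, T, P, W, q) -> np.ndarray:
    """Predict centered y for new samples from a fitted PLS1 model."""
    Xd = np.asarray(X_new, dtype=float) - x_mean
    y_hat = np.zeros(Xd.shape[0])
    for a in range(T.shape[1]):
        t = Xd @ W[:, a]
        Xd = Xd - np.outer(t, P[:, a])
        y_hat += q[a] * t
    return y_hat


def cross_validate_q2(X, y, n_components: int = 2, k: int = 10, seed: int = 0) -> float:
    """Stratified k-fold cross-validated Q2 = 1 - PRESS/TSS for PLS-DA.

    Within each fold the model is fit on the training samples (centered by
    training means); PRESS accumulates squared prediction error on held-out
    samples, TSS their squared deviation from the training-fold mean of y.
    """
    X = np.asarray(X, dtype=float)
    y01 = encode_labels(y)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    counts = np.bincount(y01.astype(int))
    k_eff = min(k, int(counts.min()))
    if k_eff < 2:
        raise ValueError("need at least 2 samples per class for stratified CV")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    press = tss = 0.0
    for train, test in skf.split(X, y01):
        x_mean = X[train].mean(axis=0)
        y_mean = y01[train].mean()
        Xt = X[train] - x_mean
        yt = y01[train] - y_mean
        T, P, W, q, _ = _nipals_pls1(Xt, yt, n_components)
        y_hat = _pls1_predict(X[test], x_mean, T, P, W, q) + y_mean
        press += float(((y01[test] - y_hat) ** 2).sum())
        tss += float(((y01[test] - y_mean) ** 2).sum())
    return 1.0 - press / tss


def oplsda(X, y, n_orthogonal: int = 1) -> LatentModel:
    """OPLS-DA: remove y-orthogonal structured variation, then fit one
    predictive PLS component on the filtered matrix."""
    X = np.asarray(X, dtype=float)
    y01 = encode_labels(y)
    yc = y01 - y01.mean()
    if n_orthogonal >= min(X.shape):
        raise ValueError(f"n_orthogonal={n_orthogonal} must be below rank bound {min(X.shape)}")
    Xd = X.copy()
    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    T_o, P_o = [], []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w      # part of the loading not aligned with w
        norm = np.linalg.norm(w_o)
        if norm < _NIPALS_TOL:
            break                  # no orthogonal variation left
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        T_o.append(t_o)
        P_o.append(p_o)
    T, P, W, q, r2y = _nipals_pls1(Xd, yc, 1)
    ssx = float((X**2).sum())
    r2x = float((T**2 * (P**2).sum(axis=0)).sum() / ssx) if ssx > 0 else 0.0
    return LatentModel(
        method="oplsda", scores=T, loadings=P, weights=W, y_loadings=q,
        orthogonal_scores=np.column_stack(T_o) if T_o else None,
        orthogonal_loadings=np.column_stack(P_o) if P_o else None,
        R2X=r2x, R2Y=r2y, n_components=1,
    )


def permutation_test(
    X,
    y,
    statistic: str = "Q2",
    n_perm: int = 1000,
    n_components: int = 2,
    k: int = 10,
    seed: int = 0,
) -> PermutationTestResult:
    """Label-permutation test of a PLS-DA model statistic (R2Y or Q2).

    The class labels are permuted uniformly ``n_perm`` times, the statistic
    recomputed for each permutation, and the empirical p reported with the
    add-one rule so it can never be zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("R2Y", "Q2"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def compute(labels) -> float:
        if statistic == "R2Y":
            return float(plsda(X, labels, n_components=n_components).R2Y)
        return cross_validate_q2(X, labels, n_components=n_components, k=k, seed=seed)

    observed = compute(y)
    null_values = np.empty(n_perm)
    for b in range(n_perm):
        null_values[b] = compute(rng.permutation(y))
    empirical_p = (float((null_values >= observed).sum()) + 1.0) / (n_perm + 1.0)
    return PermutationTestResult(statistic, observed, null_values, empirical_p)
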