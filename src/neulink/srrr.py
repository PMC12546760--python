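"""Sparse reduced-rank regression linking gene expression to model parameters.

The model predicts the 13 fitted biophysical parameters from expression of a
gene panel through a low-dimensional latent space: Y ≈ 1 μᵀ + X W Vᵀ with an
encoder W (genes × rank) and an orthonormal decoder V (targets × rank).  A
group (row-wise) elastic-net penalty on W selects genes in or out of the
model; fitting alternates a multi-task elastic-net update of W given V with
an orthogonal-Procrustes update of V given W, followed by an optional relaxed
(unpenalized) refit on the selected genes.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, MultiTaskElasticNet
from sklearn.model_selection import KFold, train_test_split

__all__ = [
    "preprocess_expression",
    "SparseRRR",
    "cross_validate_srrr",
    "per_target_r2",
    "group_average_distance",
    "classify_from_params",
]


def preprocess_expression(counts: np.ndarray, gene_names=None):
    """Depth-normalize, log-transform and z-score a cells × genes count matrix.

    Counts are scaled per cell to counts-per-million, log(1 + x) transformed,
    then each gene is z-scored across cells.  Proportional cells therefore map
    to identical rows.  All-zero genes are rejected (they carry no signal and
    would z-score to 0/0).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    zero = ~np.any(counts > 0, axis=0)
    if np.any(zero):
        names = ([gene_names[i] for i in np.flatnonzero(zero)]
                 if gene_names is not None else np.flatnonzero(zero).tolist())
        raise ValueError(f"all-zero gene(s): {names[:5]}"
                         + ("..." if len(names) > 5 else ""))
    depth = counts.sum(axis=1, keepdims=True)
    if np.any(depth == 0):
        raise ValueError("cell(s) with zero total counts")
    cpm = counts / depth * 1e6
    lg = np.log1p(cpm)
    mu, sd = lg.mean(axis=0), lg.std(axis=0)
    sd[sd == 0] = 1.0
    return (lg - mu) / sd


class SparseRRR(BaseEstimator, RegressorMixin):
    """Reduced-rank regression with group-sparse elastic-net gene selection.

    Minimizes ``||Y - X W Vᵀ||²_F / (2n) + lam (alpha Σ_g ||w_g||₂ +
    (1-alpha)/2 ||W||²_F)`` subject to ``VᵀV = I``.

    Parameters
    ----------
    rank : latent dimensionality (2 reproduces the study design;
        ``rank=None`` means full rank).
    lam : elastic-net strength; larger selects fewer genes.
    alpha : mix between the group lasso (1) and ridge (0) parts.
    relaxed : refit the selected genes without penalty after the support
        stabilizes (debiases the shrinkage).
    """

    def __init__(self, rank: int | None = 2, lam: float = 0.1, alpha: float = 0.5,
                 relaxed: bool = True, max_iter: int = 500, tol: float = 1e-6,
                 seed: int = 0):
        self.rank = rank
        self.lam = lam
        self.alpha = alpha
        self.relaxed = relaxed
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def _loss(self, X, Y, W, V):
        R = Y - X @ W @ V.T
        n = X.shape[0]
        pen = self.lam * (self.alpha * np.sum(np.linalg.norm(W, axis=1))
                          + (1 - self.alpha) / 2 * np.sum(W * W))
        return float(np.sum(R * R) / (2 * n) + pen)

    def fit(self, X, Y):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("X and Y must be fully defined")
        n, p = X.shape
        q = Y.shape[1]
        if n < 20:
            raise ValueError("need at least 20 cells")
        r = q if self.rank is None else min(self.rank, q)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc, Yc = X - self.x_mean_, Y - self.y_mean_

        # decoder init: principal right-singular directions of the covariance
        _, _, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        V = Vt[:r].T

        enet = MultiTaskElasticNet(alpha=self.lam, l1_ratio=self.alpha,
                                   fit_intercept=False, max_iter=2000,
                                   tol=1e-6)
        prev = np.inf
        W = np.zeros((p, r))
        self.n_iter_ = 0
        converged = False
        for it in range(self.max_iter):
            self.n_iter_ = it + 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                enet.fit(Xc, Yc @ V)
            W = enet.coef_.T  # (p, r)
            if not np.any(W):
                V = V  # fully shrunk; decoder arbitrary but orthonormal
                converged = True
                break
            M = Yc.T @ (Xc @ W)  # (q, r)
            P, _, Qt = np.linalg.svd(M, full_matrices=False)
            V = P @ Qt
            loss = self._loss(Xc, Yc, W, V)
            if np.isfinite(prev) and abs(prev - loss) <= self.tol * max(1.0, abs(prev)):
                converged = True
                break
            prev = loss
        if not converged:
            warnings.warn("sparse RRR did not converge; returning best iterate",
                          stacklevel=2)

        support = np.linalg.norm(W, axis=1) > 0
        if self.relaxed and support.any():
            Xs = Xc[:, support]
            B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
            # rank-r truncation of the unpenalized fit on the support
            fitted = Xs @ B
            _, _, Vt = np.linalg.svd(fitted, full_matrices=False)
            V = Vt[:r].T
            Wfull = np.zeros((p, r))
            Wfull[support] = B @ V
            W = Wfull
        self.encoder_ = W
        self.decoder_ = V
        self.support_ = support
        self.intercept_ = self.y_mean_ - self.x_mean_ @ W @ V.T
        return self

    @property
    def selected_genes_(self) -> np.ndarray:
        return np.flatnonzero(self.support_)

    @property
    def n_selected_(self) -> int:
        return int(self.support_.sum())

    def transform(self, X) -> np.ndarray:
        """Latent coordinates (cells × rank)."""
        return (np.asarray(X, float) - self.x_mean_) @ self.encoder_

    def predict(self, X) -> np.ndarray:
        return self.transform(X) @ self.decoder_.T + self.y_mean_

    def score(self, X, Y) -> float:
        """Pooled R² over all targets: 1 - SS_res / SS_tot."""
        Y = np.asarray(Y, float)
        resid = Y - self.predict(X)
        ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2)
        return float(1.0 - np.sum(resid ** 2) / ss_tot)


def cross_validate_srrr(X, Y, lam_grid, alpha: float = 0.5, rank: int | None = 2,
                        folds: int = 10, seed: int = 0, relaxed: bool = True):
    """CV curve of held-out pooled R² (and gene count) along the λ path.

    Returns a dict with arrays ``lam``, ``r2_mean``, ``r2_sd``, ``n_genes``
    (gene counts averaged over folds).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    lam_grid = np.asarray(lam_grid, float)
    r2 = np.zeros((len(lam_grid), folds))
    ngenes = np.zeros((len(lam_grid), folds))
    for j, (tr, te) in enumerate(kf.split(X)):
        for i, lam in enumerate(lam_grid):
            m = SparseRRR(rank=rank, lam=lam, alpha=alpha, relaxed=relaxed)
            m.fit(X[tr], Y[tr])
            r2[i, j] = m.score(X[te], Y[te])
            ngenes[i, j] = m.n_selected_
    return {
        "lam": lam_grid,
        "r2_mean": r2.mean(axis=1),
        "r2_sd": r2.std(axis=1),
        "n_genes": ngenes.mean(axis=1),
    }


def select_lambda(cv_result: dict, rule: str = "1se") -> float:
    """Pick λ from a :func:`cross_validate_srrr` curve.

    ``"max"`` takes the R²-maximizing λ; ``"1se"`` (default, the usual
    regularization-path convention) takes the sparsest λ whose mean R² is
    within one SD of the best — favouring parsimonious gene sets.
    """
    r2, lam = cv_result["r2_mean"], cv_result["lam"]
    best = int(np.argmax(r2))
    if rule == "max":
        return float(lam[best])
    if rule != "1se":
        raise ValueError("rule must be 'max' or '1se'")
    cutoff = r2[best] - cv_result["r2_sd"][best]
    ok = np.flatnonzero(r2 >= cutoff)
    # largest λ (fewest genes) still within one SD of the best
    return float(lam[ok[np.argmax(lam[ok])]])


def per_target_r2(Y, Y_pred) -> np.ndarray:
    """R² per target column."""
    Y, Y_pred = np.asarray(Y, float), np.asarray(Y_pred, float)
    ss_res = np.sum((Y - Y_pred) ** 2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    return 1.0 - ss_res / ss_tot


def group_average_distance(Y_map, Y_pred, labels) -> float:
    """Distance between group-averaged fitted and predicted parameter matrices.

    Both matrices are z-scored columnwise by the mean/SD of the *fitted*
    (posterior-MAP) set, rows are averaged within each label, and the
    Euclidean (Frobenius) norm of the difference of the two group-mean
    matrices is returned.
    """
    Y_map, Y_pred = np.asarray(Y_map, float), np.asarray(Y_pred, float)
    labels = np.asarray(labels)
    mu, sd = Y_map.mean(axis=0), Y_map.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Zm, Zp = (Y_map - mu) / sd, (Y_pred - mu) / sd
    groups = np.unique(labels)
    gm = np.vstack([Zm[labels == g].mean(axis=0) for g in groups])
    gp = np.vstack([Zp[labels == g].mean(axis=0) for g in groups])
    return float(np.linalg.norm(gm - gp))


def classify_from_params(Y, labels, train_fraction: float = 0.8, seed: int = 0) -> float:
    """Held-out accuracy of a multinomial logistic regression on parameters."""
    Y = np.asarray(Y, float)
    labels = np.asarray(labels)
    Ytr, Yte, ltr, lte = train_test_split(
        Y, labels, train_size=train_fraction, stratify=labels, random_state=seed)
    clf = LogisticRegression(max_iter=2000)
    clf.fit(Ytr, ltr)
    return float(clf.score(Yte, lte))
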