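"""Univariate-outcome partial least squares (PLS1) by NIPALS deflation.

The fit keeps the internal quantities of the bilinear decomposition

    X = T P' + E_X,    y = T B' + e_y

on centered/unit-scaled X and centered y: orthogonal score matrix ``T``
(n x l), X-loadings ``P`` (m x l), outcome loadings ``B`` (length l) and
projection weights ``W``.  These are exactly the ingredients of the
MSEP-based variable-contribution decomposition in :mod:`momira.contribution`,
which is why the fit is written out here rather than wrapped from a
library (scikit-learn's PLSRegression serves as an independent
cross-check in the test suite).

For a single outcome the NIPALS weight vector has the closed form
w = X'y / ||X'y||, so no inner iteration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PLSRFit:
    n_components: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray       # W, m x l
    loadings: np.ndarray      # P, m x l
    y_loadings: np.ndarray    # B, length l
    scores: np.ndarray        # T, n x l (training scores)
    rotations: np.ndarray     # R = W (P'W)^-1, m x l
    training_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)

    # -- prediction ------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scores of new samples: T_new = X_std R."""
        return self._standardize(X) @ self.rotations

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean + self.transform(X) @ self.y_loadings

    def predict_components(self, X: np.ndarray) -> np.ndarray:
        """Cumulative predictions: column s-1 uses the first s components."""
        T = self.transform(X)
        return self.y_mean + np.cumsum(T * self.y_loadings[None, :], axis=1)


def fit_plsr(X, y, n_components: int, training_ids=None, feature_ids=None) -> PLSRFit:
    """Fit PLS1 on rows-as-samples ``X`` against a numeric outcome ``y``.

    X columns are centered and scaled to unit variance (constant columns get
    unit scale), y is centered.  Raises if ``n_components`` exceeds the rank
    of the centered X or if the outcome is constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_sd[x_sd == 0] = 1.0
    Xc = (X - x_mean) / x_sd
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.empty((m, n_components))
    P = np.empty((m, n_components))
    B = np.empty(n_components)
    T = np.empty((n, n_components))
    for i in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(yc)) or nw == 0.0:
            raise ValueError(f"outcome residual exhausted after {i} components")
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        p = Xc.T @ t / tt
        b = float(t @ yc) / tt
        W[:, i], P[:, i], B[i], T[:, i] = w, p, b, t
        Xc = Xc - np.outer(t, p)
        yc = yc - b * t
    R = W @ np.linalg.inv(P.T @ W)
    return PLSRFit(n_components=n_components, x_mean=x_mean, x_sd=x_sd,
                   y_mean=y_mean, weights=W, loadings=P, y_loadings=B,
                   scores=T, rotations=R,
                   training_ids=list(training_ids) if training_ids is not None else [],
                   feature_ids=list(feature_ids) if feature_ids is not None else [])
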