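"""Attributing signature meta-features to immune-cell abundances.

Pipeline: (1) elastic-net feature selection over an (alpha, lambda) grid,
tuned by repeated k-fold cross-validated RMSE (alpha is the L1/L2 mixing
weight, lambda the penalty strength, glmnet convention); (2) an ordinary
least-squares refit on the selected cell variables gives the variance
explained; (3) LMG relative importance — each regressor's sequential sum
of squares averaged over regressor orderings — splits that R^2 into
nonnegative per-cell shares; (4) a label-permutation rerun of the whole
tuned workflow calibrates a goodness-of-fit p-value.  The pure-ridge grid
points (alpha = 0) are solved in closed form via SVD, which also yields
the whole lambda path at once.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0, 1, 11), 2))


def _standardize_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    xm, xs = X.mean(axis=0), X.std(axis=0, ddof=0)
    xs[xs == 0] = 1.0
    return (X - xm) / xs, y - y.mean()


def _lambda_grid(Xs, yc, alpha, n_lambda):
    n = len(yc)
    lmax1 = np.abs(Xs.T @ yc).max() / n
    lmax = lmax1 / max(alpha, 0.001)
    return np.geomspace(lmax, lmax * 1e-4, n_lambda)


def _ridge_path(Xtr, ytr, Xval, lambdas):
    """Closed-form ridge coefficients/predictions for a whole lambda path."""
    n = len(ytr)
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    uy = U.T @ ytr
    shrink = s[:, None] / (s[:, None] ** 2 + n * lambdas[None, :])
    W = Vt.T @ (shrink * uy[:, None])          # p x n_lambda
    return Xval @ W, W


def _enet_path(Xtr, ytr, Xval, alpha, lambdas):
    if alpha == 0:
        return _ridge_path(Xtr, ytr, Xval, lambdas)
    order = np.argsort(lambdas)[::-1]            # path wants descending penalties
    _, coefs_d, _ = enet_path(Xtr, ytr, l1_ratio=alpha, alphas=lambdas[order],
                              tol=1e-8, max_iter=10000)
    coefs = np.empty_like(coefs_d)
    coefs[:, order] = coefs_d
    return Xval @ coefs, coefs


def elasticnet_select(y, X, alpha_grid=DEFAULT_ALPHA_GRID, lambda_grid=None,
                      n_lambda: int = 50, cv: int = 10, repeats: int = 3,
                      seed: int = 0) -> dict:
    """Tune (alpha, lambda) by repeated k-fold CV RMSE; return the selection.

    ``lambda_grid`` overrides the data-driven per-alpha path (a geometric
    sequence from the smallest penalty that zeroes every coefficient).
    Returns a dict with ``selected`` (regressor names or indices with
    nonzero coefficients in the full-data refit at the winning pair),
    ``alpha``, ``lambda``, ``cv_rmse`` and the full grid of CV RMSEs.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
    Xs, yc = _standardize_xy(X, y)
    n = len(yc)
    if n <= 10:
        raise ValueError("need more than 10 samples")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    folds = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        folds.extend(np.array_split(perm, cv))
    fold_rep = [i // cv for i in range(len(folds))]

    results = {}
    for alpha in alpha_grid:
        lambdas = np.asarray(lambda_grid, dtype=float) if lambda_grid is not None \
            else _lambda_grid(Xs, yc, alpha, n_lambda)
        sse = np.zeros(len(lambdas))
        rmses = np.zeros(len(lambdas))
        n_folds = 0
        for val_idx in folds:
            tr_mask = np.ones(n, bool)
            tr_mask[val_idx] = False
            preds, _ = _enet_path(Xs[tr_mask], yc[tr_mask], Xs[val_idx], alpha, lambdas)
            rmses += np.sqrt(np.mean((preds - yc[val_idx, None]) ** 2, axis=0))
            n_folds += 1
        rmses /= n_folds
        results[alpha] = (lambdas, rmses)

    best = min(((a, j) for a, (ls, rs) in results.items() for j in range(len(ls))),
               key=lambda aj: (results[aj[0]][1][aj[1]], aj[0], aj[1]))
    alpha, j = best
    lam = float(results[alpha][0][j])
    cv_rmse = float(results[alpha][1][j])
    _, coefs = _enet_path(Xs, yc, Xs[:0], alpha, np.array([lam]))
    nz = np.abs(coefs[:, 0]) > 1e-8
    return {"selected": [names[i] for i in np.flatnonzero(nz)],
            "alpha": float(alpha), "lambda": lam, "cv_rmse": cv_rmse,
            "coef": pd.Series(coefs[:, 0], index=names),
            "grid": {a: (ls.tolist(), rs.tolist()) for a, (ls, rs) in results.items()}}


# ------------------------------------------------------------------ refits

def refit_variance_explained(y, X_selected) -> float:
    """OLS R^2 of the meta-feature on the selected cell variables."""
    X = np.asarray(X_selected, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        raise ValueError("empty selection")
    D = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        import warnings
        warnings.warn("collinear selected set; using pseudo-inverse", stacklevel=2)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss)


def _subset_r2_table(Xs, yc):
    """R^2 for every regressor subset, indexed by bitmask."""
    p = Xs.shape[1]
    C = Xs.T @ Xs
    c = Xs.T @ yc
    tss = float(yc @ yc)
    r2 = np.zeros(1 << p)
    for mask in range(1, 1 << p):
        idx = [i for i in range(p) if mask >> i & 1]
        sol = np.linalg.lstsq(C[np.ix_(idx, idx)], c[idx], rcond=None)[0]
        r2[mask] = float(c[idx] @ sol) / tss
    return r2


def lmg_importance(y, X_selected, max_exact: int = 15, n_orderings: int = 5000,
                   seed: int = 0):
    """LMG relative importance: sequential R^2 gains averaged over orderings.

    Exact enumeration over the subset lattice for p <= ``max_exact``;
    Monte-Carlo over ``n_orderings`` random orderings beyond that.  Shares
    are nonnegative for OLS fits and sum to the full-model R^2.
    """
    names = list(X_selected.columns) if isinstance(X_selected, pd.DataFrame) \
        else list(range(np.shape(X_selected)[1]))
    Xs, yc = _standardize_xy(X_selected, y)
    p = Xs.shape[1]
    if p == 0:
        raise ValueError("no regressors")
    if p <= max_exact:
        r2 = _subset_r2_table(Xs, yc)
        shares = np.zeros(p)
        fact = [math.factorial(k) for k in range(p + 1)]
        for i in range(p):
            for mask in range(1 << p):
                if mask >> i & 1:
                    continue
                k = bin(mask).count("1")
                w = fact[k] * fact[p - 1 - k] / fact[p]
                shares[i] += w * (r2[mask | (1 << i)] - r2[mask])
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
        C = Xs.T @ Xs
        c = Xs.T @ yc
        tss = float(yc @ yc)
        shares = np.zeros(p)
        for _ in range(n_orderings):
            order = rng.permutation(p)
            prev = 0.0
            for k in range(1, p + 1):
                idx = sorted(order[:k])
                sol = np.linalg.lstsq(C[np.ix_(idx, idx)], c[idx], rcond=None)[0]
                cur = float(c[idx] @ sol) / tss
                shares[order[k - 1]] += cur - prev
                prev = cur
        shares /= n_orderings
    return pd.Series(shares, index=names, name="lmg_share")


def permutation_gof(y, X, n_perm: int = 1000, seed: int = 0, **select_kwargs) -> dict:
    """Goodness-of-fit p-value by permuting the response.

    Each permutation reruns the full tuned workflow (including
    hyperparameter selection); the p-value compares the observed best CV
    RMSE against the permuted-null RMSE distribution with add-one
    smoothing, so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    obs = elasticnet_select(y, X, seed=seed, **select_kwargs)["cv_rmse"]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        null[i] = elasticnet_select(yp, X, seed=seed + i + 1, **select_kwargs)["cv_rmse"]
    p = (1 + int(np.sum(null <= obs))) / (n_perm + 1)
    return {"p": float(p), "observed_rmse": float(obs), "null_rmse": null}


def diagnosis_partial_r2(y, diagnosis, X_cells) -> dict:
    """Variance in a meta-feature explained by diagnosis, +- cell adjustment.

    ``r2_unadjusted`` regresses the raw meta-feature on the case/control
    indicator; ``r2_adjusted`` first removes the cell-count fit by OLS and
    regresses the residuals.  The F test for the adjusted effect uses
    df2 = n - 2 - p_cells, charging the cell regression for its degrees of
    freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    d = np.asarray(diagnosis)
    if d.dtype.kind in "UO":
        d = (d == "RA").astype(float)
    d = d.astype(float)
    if len(np.unique(d)) < 2:
        raise ValueError("both diagnoses required")
    X = np.asarray(X_cells, dtype=float)
    r2_unadj = refit_variance_explained(y, d[:, None])
    D = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    if resid.var() <= 1e-12 * y.var():
        # cells explain the response completely; nothing left for diagnosis
        return {"r2_unadjusted": float(r2_unadj), "r2_adjusted": 0.0, "p": 1.0}
    r2_adj = refit_variance_explained(resid, d[:, None])
    df2 = len(y) - 2 - X.shape[1]
    f = (r2_adj / 1) / ((1 - r2_adj) / df2)
    p = float(stats.f.sf(f, 1, df2))
    return {"r2_unadjusted": float(r2_unadj), "r2_adjusted": float(r2_adj), "p": p}


def shared_effect_test(scores, diagnosis, cell_type) -> dict:
    """Mixed-model test of a disease effect shared across cell types.

    score ~ diagnosis (fixed) with a random intercept per cell type;
    returns the Wald p for the fixed diagnosis effect.
    """
    import warnings

    import statsmodels.api as sm

    y = np.asarray(scores, dtype=float).ravel()
    d = np.asarray(diagnosis)
    if d.dtype.kind in "UO":
        d = (d == "RA").astype(float)
    cell = np.asarray(cell_type)
    if len(np.unique(cell)) < 3:
        raise ValueError("need at least 3 cell types")
    if len(np.unique(d)) < 2:
        raise ValueError("both diagnoses required")
    exog = np.column_stack([np.ones(len(y)), d.astype(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MixedLM(y, exog, groups=cell).fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ValueError(f"singular mixed-model fit: {err}") from err
    return {"p": float(fit.pvalues[1]), "effect": float(fit.fe_params[1])}
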