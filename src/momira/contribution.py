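"""Variable-contribution decomposition of a PLS1 diagnostic.

The importance of a feature is built in three steps from a fitted model's
internal quantities, evaluated on the member's own training fold (where
the orthogonal scores T are defined without projection ambiguity):

1. partial predictions f_s(k) = y_mean + sum_{i<=s} t_ki b_i, and their
   mean squared error of prediction MSEP_s (MSEP_0 is the variance of y
   around the training mean);
2. component weights w_s = (MSEP_s - MSEP_{s-1}) / sum_i (MSEP_i -
   MSEP_{i-1}) — the share of the total MSEP reduction delivered by the
   s-th orthogonal component (weights are signed: a component that
   increases MSEP gets a negative weight and the vector still sums to 1);
3. per-feature contributions g_i = (1/l) sum_j p_ij w_j, normalized to
   r_i = g_i / sum_j g_j and rescaled so the maximum r is 100.

Ensemble contributions are the arithmetic mean of the per-member scaled r
vectors; the member-to-member spread is the reported uncertainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .plsr import PLSRFit


def component_prediction(fit: PLSRFit, X, s: int) -> np.ndarray:
    """Partial prediction from the first ``s`` orthogonal components.

    ``s = 0`` is the intercept-only prediction (training mean of y).
    """
    if not 0 <= s <= fit.n_components:
        raise ValueError(f"s={s} outside [0, {fit.n_components}]")
    X = np.asarray(X, dtype=float)
    if s == 0:
        return np.full(X.shape[0], fit.y_mean)
    T = fit.transform(X)
    return fit.y_mean + T[:, :s] @ fit.y_loadings[:s]


def msep(fit: PLSRFit, X, y, s: int) -> float:
    """Mean squared error of prediction using ``s`` components."""
    y = np.asarray(y, dtype=float).ravel()
    f = component_prediction(fit, X, s)
    if len(f) != len(y):
        raise ValueError("X and y disagree on sample count")
    return float(np.mean((f - y) ** 2))


def component_weights(fit: PLSRFit, X, y) -> np.ndarray:
    """Relative contribution of each orthogonal component to the prediction."""
    l = fit.n_components
    mseps = np.array([msep(fit, X, y, s) for s in range(l + 1)])
    increments = np.diff(mseps)                    # MSEP_s - MSEP_{s-1}
    denom = mseps[l] - mseps[0]                    # telescoping sum
    if denom == 0:
        raise ValueError("total MSEP change is zero; component weights undefined")
    return increments / denom


def variable_contribution(fit: PLSRFit, X, y, absolute: bool = False):
    """Per-feature contributions (g, r); r is max-scaled to 100.

    ``absolute=True`` takes |g| before normalization for users who want
    sign-free importances; the default keeps the signed formulas.
    """
    w = component_weights(fit, X, y)
    g = (fit.loadings * w[None, :]).mean(axis=1)   # (1/l) sum_j p_ij w_j
    if absolute:
        g = np.abs(g)
    total = g.sum()
    if total == 0:
        raise ValueError("sum of contributions is zero; r undefined")
    r = g / total
    r = r * (100.0 / r.max())
    return g, r


def ensemble_contribution(model: EnsembleModel, layer_values: pd.DataFrame,
                          labels: pd.Series, absolute: bool = False) -> pd.DataFrame:
    """Mean scaled contribution per feature across ensemble members.

    ``layer_values`` is the feature x sample matrix the ensemble was
    trained on; each member is evaluated on its own training fold.
    Returns a DataFrame (feature_id, r_mean, r_sd) sorted by descending
    r_mean.
    """
    R = np.empty((len(model.members), len(model.feature_ids)))
    X_all = layer_values.loc[model.feature_ids]
    for i, member in enumerate(model.members):
        X = X_all[member.train_ids].T.to_numpy(dtype=float)
        y = labels.loc[member.train_ids].to_numpy(dtype=float)
        _, R[i] = variable_contribution(member.fit, X, y, absolute=absolute)
    out = pd.DataFrame({
        "feature_id": model.feature_ids,
        "r_mean": R.mean(axis=0),
        "r_sd": R.std(axis=0, ddof=1),
    })
    return out.sort_values("r_mean", ascending=False, ignore_index=True)


def important_features(contrib: pd.DataFrame, threshold: float = 50.0) -> list:
    """Features whose mean importance exceeds ``threshold`` (default 50)."""
    return list(contrib.loc[contrib["r_mean"] > threshold, "feature_id"])
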