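"""Moderated-t differential analysis and longitudinal trajectory testing.

Per-feature linear models with nuisance covariates are fitted by ordinary
least squares; the residual variances are shrunk toward a common prior by
empirical Bayes, with the prior (d0, s0^2) obtained by method-of-moments
matching of a scaled inverse-chi-square distribution on the log-variance
scale (digamma/trigamma moment equations).  The moderated t statistic uses
the shrunk variance and d + d0 degrees of freedom.  False-discovery rates
are Benjamini-Hochberg step-up q-values (pi0 = 1, a conservative stand-in
for Storey's estimator); the significance gate requires BOTH p and q below
their thresholds.

The trajectory test fits a linear mixed model: cubic B-spline fixed
effects of time with a random intercept per subject, and tests the spline
coefficients jointly by a likelihood-ratio test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.interpolate import BSpline

from .datatypes import OmicsLayer, SignatureSet

DE_COLUMNS = ("feature_id", "coef", "t", "p", "q", "direction")


# ----------------------------------------------------- empirical Bayes fit

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/y scale)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float):
    """Method-of-moments prior (d0, s0^2) for residual variances.

    Matches the mean and variance of log(s^2) against the scaled
    inverse-chi-square model; returns ``d0 = inf`` when the observed
    log-variances are less dispersed than pure chi-square noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2))
    if excess > 0:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2 * half_d0
        s0_2 = np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0))
    else:
        # log-variances no more dispersed than chi-square noise: complete
        # shrinkage to the pooled (arithmetic mean) variance
        d0 = np.inf
        s0_2 = float(s2[ok].mean())
    return float(d0), float(s0_2)


def _moderated_fit(Y: np.ndarray, D: np.ndarray, coef_idx: int, prior_df=None):
    """OLS per row of Y against design D; moderated t on column coef_idx."""
    n, q = D.shape
    df = n - q
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(D) < q:
        raise ValueError("rank-deficient design")
    if prior_df == 0 and df < 3:
        raise ValueError("fewer than 3 residual df and no variance shrinkage")
    DtD_inv = np.linalg.inv(D.T @ D)
    H = DtD_inv @ D.T
    beta = Y @ H.T                          # features x q
    resid = Y - beta @ D.T
    s2 = (resid ** 2).sum(axis=1) / df
    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 1.0
    else:
        d0, s0_2 = float(prior_df), float(np.median(s2))
    df_pooled = df * Y.shape[0]              # cap: total information available
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = df_pooled
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = min(df + d0, df_pooled)
    se = np.sqrt(np.maximum(s2_post, 1e-300) * DtD_inv[coef_idx, coef_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, coef_idx] / se
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return beta[:, coef_idx], t, p


def _finish_table(feature_ids, coef, t, p) -> pd.DataFrame:
    q = fdr(p)
    direction = np.sign(coef).astype(int)
    return pd.DataFrame({"feature_id": list(feature_ids), "coef": coef,
                         "t": t, "p": p, "q": q, "direction": direction})


# --------------------------------------------------------- public contrasts

def moderated_ttest(layer: OmicsLayer, meta: pd.DataFrame,
                    group_var: str = "diagnosis", covariates=("age",),
                    prior_df=None) -> pd.DataFrame:
    """Two-group moderated t-test with nuisance covariates.

    ``group_var`` must be binary over the supplied samples; the returned
    coefficient is the second-level-minus-first-level effect (for
    ``diagnosis``: RA minus HC).
    """
    meta_i = meta.set_index("sample_id").loc[layer.sample_ids]
    levels = sorted(meta_i[group_var].unique())
    if len(levels) != 2:
        raise ValueError(f"{group_var} is not binary over these samples")
    if group_var == "diagnosis":
        levels = ["HC", "RA"]
    g = (meta_i[group_var] == levels[1]).astype(float).to_numpy()
    cols = [np.ones(len(meta_i)), g]
    for c in covariates:
        v = (meta_i["gender"] == "M").astype(float) if c == "gender" else meta_i[c]
        cols.append(np.asarray(v, dtype=float))
    D = np.column_stack(cols)
    Y = layer.values.to_numpy(dtype=float)
    coef, t, p = _moderated_fit(Y, D, coef_idx=1, prior_df=prior_df)
    return _finish_table(layer.feature_ids, coef, t, p)


def paired_contrast(layer: OmicsLayer, meta: pd.DataFrame, week_a: int, week_b: int,
                    covariates=(), prior_df=None) -> pd.DataFrame:
    """Within-subject contrast week_b - week_a; subject enters as a block factor."""
    meta_i = meta.set_index("sample_id").loc[layer.sample_ids]
    meta_i = meta_i[meta_i["week"].isin([week_a, week_b])]
    counts = meta_i.groupby("subject_id")["week"].nunique()
    paired = counts.index[counts == 2]
    dropped = set(counts.index) - set(paired)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} unpaired subjects", stacklevel=2)
    meta_i = meta_i[meta_i["subject_id"].isin(paired)]
    if meta_i.empty:
        raise ValueError("no paired subjects")
    ids = list(meta_i.index)
    subj = pd.get_dummies(meta_i["subject_id"], drop_first=True).to_numpy(dtype=float)
    wk = (meta_i["week"] == week_b).astype(float).to_numpy()
    cols = [np.ones(len(ids)), wk]
    for c in covariates:
        cols.append(np.asarray(meta_i[c], dtype=float))
    D = np.column_stack(cols + [subj])
    Y = layer.values[ids].to_numpy(dtype=float)
    coef, t, p = _moderated_fit(Y, D, coef_idx=1, prior_df=prior_df)
    return _finish_table(layer.feature_ids, coef, t, p)


def fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_gate(de: pd.DataFrame, p_max: float = 0.05, q_max: float = 0.05,
                      layer: str = "transcript", stage: str = "custom") -> SignatureSet:
    """Features passing BOTH p and q thresholds, split by effect direction."""
    hit = de[(de["p"] < p_max) & (de["q"] < q_max)]
    return SignatureSet(layer=layer,
                        up=frozenset(hit.loc[hit["direction"] > 0, "feature_id"]),
                        down=frozenset(hit.loc[hit["direction"] < 0, "feature_id"]),
                        stage=stage,
                        provenance={"p_max": p_max, "q_max": q_max, "n_tested": len(de)})


# ----------------------------------------------------- trajectory modeling

def bspline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Cubic B-spline basis with boundary knots at min/max x.

    ``df`` columns excluding the intercept; ``df - 3`` interior knots at
    quantiles of x (the default df=3 has none).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("time variable is constant")
    n_interior = max(df - 3, 0)
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else []
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    B = BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
    return B[:, 1:]        # drop one column; the intercept spans the rest


def spline_trajectory_test(values, week, subject, df: int = 3) -> dict:
    """Random-intercept mixed model test of any time trend.

    Fixed effects are ``df`` cubic B-spline functions of week (collinear
    columns dropped automatically when few distinct weeks are observed);
    subjects contribute random intercepts.  Returns the LRT p-value for the
    joint nullity of the spline coefficients, plus diagnostics.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    week = np.asarray(week, dtype=float)
    subject = np.asarray(subject)
    if len(np.unique(week)) < 3:
        raise ValueError("need at least 3 distinct weeks")
    if np.ptp(y) == 0:
        raise ValueError("degenerate input: response is constant")
    B = bspline_basis(week, df=df)
    # drop columns collinear with the intercept / each other
    full = np.column_stack([np.ones(len(y)), B])
    _, R = np.linalg.qr(full)
    keep = np.abs(np.diag(R)) > 1e-8 * np.abs(R[0, 0])
    exog = full[:, keep]
    n_spline = exog.shape[1] - 1
    if n_spline < 1:
        raise ValueError("spline basis collinear with intercept")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full_fit = sm.MixedLM(y, exog, groups=subject).fit(reml=False)
            null_fit = sm.MixedLM(y, exog[:, :1], groups=subject).fit(reml=False)
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ValueError(f"singular mixed-model fit: {err}") from err
    lrt = 2 * (full_fit.llf - null_fit.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), n_spline))
    return {"p": p, "lrt": float(lrt), "df": int(n_spline),
            "coefficients": np.asarray(full_fit.fe_params)[1:]}
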