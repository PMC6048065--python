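"""Cross-study signature overlap statistics.

Fisher's exact test on 2x2 set-membership tables against a common feature
universe, Stouffer z-score combination of per-study evidence for the same
disease, and fold-change concordance between matched signature vectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

#: reported in place of an infinite conditional-MLE odds ratio
OR_CAP = 1e12


def fisher_overlap(setA, setB, universe) -> tuple[float, float]:
    """Two-sided Fisher exact test of set overlap within a universe.

    Returns (odds_ratio, p); the odds ratio is the conditional MLE, capped
    at :data:`OR_CAP` when degenerate.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A, B = set(setA) & universe, set(setB) & universe
    if set(setA) - universe or set(setB) - universe:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(A & B)
    n12 = len(A - B)
    n21 = len(B - A)
    n22 = len(universe) - n11 - n12 - n21
    table = [[n11, n12], [n21, n22]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    orr = _cond_odds_ratio(table, kind="conditional").statistic
    if not np.isfinite(orr):
        orr = OR_CAP
    return float(orr), p


def stouffer_combine(p_values, effect_directions, two_sided: bool = True):
    """Stouffer's direction-aware z combination across studies.

    z_i = sign_i * probit of the (one-sided) evidence; with two-sided input
    p-values, z_i = sign_i * Phi^-1(1 - p_i/2).  The combined statistic is
    sum(z_i)/sqrt(k); the returned p is two-sided.
    """
    p = np.asarray(p_values, dtype=float)
    sign = np.sign(np.asarray(effect_directions, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values clamped away from 0/1", stacklevel=2)
        eps = np.finfo(float).tiny
        p = np.clip(p, eps, 1 - 1e-16)
    tail = p / 2 if two_sided else p
    z = sign * stats.norm.isf(tail)
    z_comb = float(z.sum() / np.sqrt(len(z)))
    p_comb = float(2 * stats.norm.sf(abs(z_comb)))
    return z_comb, p_comb


def combine_studies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-disease Stouffer combination of a study table.

    Expects columns study_id, disease_tag, direction, p; returns one row
    per disease with the combined z and two-sided p, plus the +-2.5%
    quantile flag over the resulting z distribution.
    """
    rows = []
    for disease, grp in table.groupby("disease_tag"):
        z, p = stouffer_combine(grp["p"].to_numpy(), grp["direction"].to_numpy())
        rows.append({"disease_tag": disease, "n_studies": len(grp),
                     "z": z, "p": p})
    out = pd.DataFrame(rows).sort_values("z", ascending=False, ignore_index=True)
    lo, hi = np.quantile(out["z"], [0.025, 0.975])
    out["extreme"] = (out["z"] < lo) | (out["z"] > hi)
    return out


def foldchange_concordance(fc_a: pd.Series, fc_b: pd.Series) -> dict:
    """Pearson and Spearman correlation of matched log fold changes."""
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared features")
    a = fc_a.loc[shared].to_numpy(dtype=float)
    b = fc_b.loc[shared].to_numpy(dtype=float)
    return {"pearson": float(stats.pearsonr(a, b)[0]),
            "spearman": float(stats.spearmanr(a, b)[0]),
            "n_shared": int(len(shared))}
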