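"""Single-sample gene-set enrichment (ssGSEA) meta-features.

A signature's per-sample score is the integrated difference between the
weighted in-set running ECDF and the unweighted out-set running ECDF along
the expression ranking of that sample: features are ranked (average ranks
for ties), walked in decreasing order, in-set steps are weighted by
rank^tau (tau = 0.25), and the score is the sum of the running
differences.  Scores are rank-based, hence invariant to any strictly
monotone transform of a sample's values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import OmicsLayer, SignatureSet


def ssgsea_sample(values: np.ndarray, in_set: np.ndarray, tau: float = 0.25) -> float:
    """Score one sample; ``in_set`` is a boolean mask over features."""
    ranks = rankdata(values, method="average")
    order = np.argsort(-ranks, kind="mergesort")
    r_sorted = ranks[order]
    member = in_set[order]
    w = np.where(member, r_sorted ** tau, 0.0)
    denom_in = w.sum()
    n_out = (~member).sum()
    if denom_in == 0 or n_out == 0:
        raise ValueError("signature empty or spanning all features")
    ecdf_in = np.cumsum(w) / denom_in
    ecdf_out = np.cumsum(~member) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(layer: OmicsLayer, signatures, tau: float = 0.25) -> pd.DataFrame:
    """Scores for each signature set (rows) across samples (columns).

    ``signatures`` is a list of SignatureSets — scored separately per
    direction as ``<layer>_<stage>_<up|down>`` — or a dict name -> feature
    id collection.
    """
    named = {}
    if isinstance(signatures, dict):
        named = {k: set(v) for k, v in signatures.items()}
    else:
        for sig in signatures:
            for direction in ("up", "down"):
                members = getattr(sig, direction)
                if members:
                    named[f"{sig.layer}_{sig.stage}_{direction}"] = set(members)
    feats = pd.Index(layer.feature_ids)
    X = layer.values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, X)       # feature ranks per sample
    scores = {}
    for name, members in named.items():
        mask = feats.isin(members)
        if mask.sum() < 2:
            raise ValueError(f"signature {name!r} has fewer than 2 features in layer")
        scores[name] = [_score_from_ranks(ranks[:, j], mask, tau)
                        for j in range(X.shape[1])]
    return pd.DataFrame(scores, index=layer.sample_ids).T


def _score_from_ranks(ranks: np.ndarray, mask: np.ndarray, tau: float) -> float:
    order = np.argsort(-ranks, kind="mergesort")
    member = mask[order]
    w = np.where(member, ranks[order] ** tau, 0.0)
    n_out = (~member).sum()
    if n_out == 0:
        raise ValueError("signature spans all features")
    ecdf_in = np.cumsum(w) / w.sum()
    ecdf_out = np.cumsum(~member) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def standardize(scores: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Z-score along ``axis`` (1 = across samples/columns, 0 = across rows)."""
    if scores.shape[1 - axis] < 1 or scores.shape[axis] < 2:
        raise ValueError("need at least 2 entries along the standardization axis")
    if axis == 1:
        mu, sd = scores.mean(axis=1), scores.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValueError("zero variance row; cannot standardize")
        return scores.sub(mu, axis=0).div(sd, axis=0)
    mu, sd = scores.mean(axis=0), scores.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero variance column; cannot standardize")
    return scores.sub(mu, axis=1).div(sd, axis=1)


def cell_specificity_report(reference: OmicsLayer, signatures, tau: float = 0.25) -> pd.DataFrame:
    """Which purified cell types express a signature most highly.

    Scores every signature against each reference column (one per cell
    type), standardizes across cell types, and returns a long table sorted
    by z within signature.
    """
    scores = ssgsea(reference, signatures, tau=tau)
    z = standardize(scores, axis=1)
    rows = []
    for sig in z.index:
        ranked = z.loc[sig].sort_values(ascending=False)
        for rank, (cell, val) in enumerate(ranked.items(), start=1):
            rows.append({"signature": sig, "cell_type": cell,
                         "z": float(val), "rank": rank})
    return pd.DataFrame(rows)
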