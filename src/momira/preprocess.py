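"""Feature QC, bridge-replicate batch adjustment and covariate removal.

The processing order is batch adjustment -> covariate regression-out ->
feature filtering, applied per layer: batch distortions are purely
technical and must be removed before any coefficient estimation.

Batch adjustment is a direct location/scale match on bridge replicates
(identical biological samples assayed in every batch): per feature, each
non-reference batch is shifted and rescaled so its bridge replicates agree
with the reference batch (lowest batch id).  Covariate models are fitted
once on training samples and the same coefficients are reused verbatim on
held-out or treated samples; the disease label participates in the fit but
only nuisance coefficients (age, gender, RIN, ...) are subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsLayer


# ---------------------------------------------------------------- filtering

def filter_features(layer: OmicsLayer,
                    presence_max_absent_frac: float = 1 / 3,
                    collapse_map: dict | None = None,
                    corr_threshold: float = 0.3,
                    iqr_bottom_frac: float = 0.2):
    """Stepwise feature QC.

    Applies, in order: (1) drop features without a (unique) gene mapping
    when a collapse map is given; (2) drop features flagged absent in more
    than ``presence_max_absent_frac`` of samples; (3) for genes measured by
    several mutually correlated features (Pearson r > ``corr_threshold``),
    keep the feature with the highest mean signal; (4) drop the least
    variable features, i.e. the bottom ``iqr_bottom_frac`` of interquartile
    ranges.

    Returns the filtered layer and an audit log of per-step removals.
    """
    X = layer.values
    audit = {"input": len(X)}

    keep = pd.Index(X.index)
    if collapse_map is not None:
        genes = pd.Series(collapse_map)
        mapped = keep.intersection(genes.index)
        multi = genes.loc[mapped].astype(str).str.contains(r"[;,/]")
        keep = mapped[~multi.to_numpy()]
    audit["unmapped_removed"] = audit["input"] - len(keep)

    if layer.presence is not None:
        absent_frac = 1.0 - layer.presence.loc[keep].mean(axis=1)
        keep = keep[(absent_frac <= presence_max_absent_frac).to_numpy()]
    audit["absent_removed"] = audit["input"] - audit["unmapped_removed"] - len(keep)

    n_before = len(keep)
    if collapse_map is not None and corr_threshold < 1.0:
        keep = _collapse_by_gene(X.loc[keep], {f: collapse_map[f] for f in keep},
                                 corr_threshold)
    audit["collapsed_removed"] = n_before - len(keep)

    n_before = len(keep)
    if iqr_bottom_frac > 0 and len(keep):
        sub = X.loc[keep]
        iqr = sub.quantile(0.75, axis=1) - sub.quantile(0.25, axis=1)
        cutoff = iqr.quantile(iqr_bottom_frac)
        keep = keep[(iqr > cutoff).to_numpy()]
    audit["low_iqr_removed"] = n_before - len(keep)
    audit["output"] = len(keep)

    if len(keep) == 0:
        raise ValueError("feature filtering removed every feature")
    return layer.subset_features(keep), audit


def _collapse_by_gene(X: pd.DataFrame, fmap: dict, corr_threshold: float) -> pd.Index:
    keep = []
    by_gene: dict = {}
    for f in X.index:
        by_gene.setdefault(fmap[f], []).append(f)
    for gene, feats in by_gene.items():
        if len(feats) == 1:
            keep.append(feats[0])
            continue
        # pairwise-complete Pearson correlation across QC-passing samples
        corr = X.loc[feats].T.corr()
        means = X.loc[feats].mean(axis=1)
        remaining = set(feats)
        while remaining:
            rem = sorted(remaining)
            # cluster = the current best feature plus everything correlated with it
            best = min(rem, key=lambda f: (-means[f], f))   # ties -> smallest id
            group = [f for f in rem if f == best or corr.loc[best, f] > corr_threshold]
            keep.append(best)
            remaining -= set(group)
    return pd.Index([f for f in X.index if f in set(keep)])


# ------------------------------------------------------------- batch model

@dataclass
class BatchModel:
    """Per-feature location shift and scale factor per batch, bridge-estimated."""

    reference_batch: int
    location: pd.DataFrame     # feature x batch: bridge mean per batch
    scale: pd.DataFrame        # feature x batch: bridge SD ratio vs reference
    min_scale: float = 1e-8


def fit_batch_model(layer: OmicsLayer, meta: pd.DataFrame, scale: bool = True) -> BatchModel:
    """Estimate batch location/scale from bridge replicates.

    Requires at least 2 bridge samples in every batch; the lowest batch id
    is the reference.
    """
    meta = meta.set_index("sample_id").loc[layer.sample_ids]
    batches = sorted(meta["batch"].unique())
    ref = batches[0]
    bridge = meta[meta["bridge"]]
    loc, sc = {}, {}
    for b in batches:
        ids = bridge.index[bridge["batch"] == b]
        if len(ids) < 2:
            raise ValueError(f"batch {b} has fewer than 2 bridge samples")
        sub = layer.values[list(ids)]
        loc[b] = sub.mean(axis=1)
        sc[b] = sub.std(axis=1, ddof=1)
    location = pd.DataFrame(loc)
    sds = pd.DataFrame(sc)
    if scale:
        ratio = sds.div(sds[ref], axis=0)
        ratio = ratio.where(np.isfinite(ratio) & (ratio > 1e-8), 1.0)
    else:
        ratio = pd.DataFrame(1.0, index=location.index, columns=location.columns)
    return BatchModel(reference_batch=ref, location=location, scale=ratio)


def apply_batch_model(layer: OmicsLayer, meta: pd.DataFrame, model: BatchModel) -> OmicsLayer:
    """Map every batch onto the reference batch: x -> (x - mu_b)/s_b + mu_ref."""
    meta = meta.set_index("sample_id").loc[layer.sample_ids]
    X = layer.values.to_numpy(dtype=float).copy()
    ref = model.reference_batch
    mu_ref = model.location[ref].to_numpy()
    for b in model.location.columns:
        if b == ref:
            continue
        cols = np.flatnonzero((meta["batch"] == b).to_numpy())
        if len(cols) == 0:
            continue
        mu_b = model.location[b].to_numpy()
        s_b = model.scale[b].to_numpy()
        X[:, cols] = (X[:, cols] - mu_b[:, None]) / s_b[:, None] + mu_ref[:, None]
    out = pd.DataFrame(X, index=layer.values.index, columns=layer.values.columns)
    return OmicsLayer(layer.layer, out, layer.presence)


def drop_bridge_replicates(layer: OmicsLayer, meta: pd.DataFrame):
    """Keep one copy of each bridge subject: the copy from the latest batch.

    Mirrors the rule that when replicates are available the second batch's
    data are used.  Returns (layer, meta) with replicate columns removed and
    the surviving copy renamed to the plain sample id.
    """
    meta = meta.copy()
    key = meta["sample_id"].str.replace(r"\.br\d+$", "", regex=True)
    meta["_base"] = key
    keep_rows = meta.sort_values("batch").groupby("_base", sort=False).tail(1)
    keep_rows = keep_rows.set_index("sample_id").loc[[s for s in layer.sample_ids
                                                      if s in set(keep_rows["sample_id"])]]
    sub = layer.subset_samples(list(keep_rows.index))
    rename = dict(zip(keep_rows.index, keep_rows["_base"]))
    values = sub.values.rename(columns=rename)
    presence = sub.presence.rename(columns=rename) if sub.presence is not None else None
    out_meta = keep_rows.reset_index()
    out_meta["sample_id"] = out_meta["sample_id"].map(rename)
    out_meta = out_meta.drop(columns="_base")
    return OmicsLayer(layer.layer, values, presence), out_meta


# --------------------------------------------------------- covariate model

@dataclass
class CovariateModel:
    """Per-feature linear coefficients for nuisance covariates.

    The design includes the disease label so nuisance estimates are not
    contaminated by case/control differences, but only the nuisance columns
    are subtracted when the model is applied.
    """

    covariates: list
    coef: pd.DataFrame          # feature x (intercept + covariates + diagnosis)
    centers: pd.Series          # training means of the numeric covariates
    training_ids: list = field(default_factory=list)


def _design(meta: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(meta))}
    for c in covariates:
        if c == "gender":
            cols["gender"] = (meta["gender"] == "M").astype(float).to_numpy()
        else:
            cols[c] = meta[c].to_numpy(dtype=float)
    cols["diagnosis"] = (meta["diagnosis"] == "RA").astype(float).to_numpy()
    return pd.DataFrame(cols, index=meta["sample_id"])


def fit_covariate_model(layer: OmicsLayer, meta: pd.DataFrame, covariates,
                        training_ids) -> CovariateModel:
    training_ids = list(training_ids)
    meta_tr = meta.set_index("sample_id").loc[training_ids].reset_index()
    if meta_tr["diagnosis"].nunique() < 2:
        raise ValueError("training ids must include both diagnoses")
    D = _design(meta_tr, covariates)
    if np.linalg.matrix_rank(D.to_numpy()) < D.shape[1]:
        raise ValueError("rank-deficient covariate design")
    Y = layer.values[training_ids].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(D.to_numpy(), Y.T, rcond=None)
    coef = pd.DataFrame(beta.T, index=layer.values.index, columns=D.columns)
    centers = D.drop(columns=["intercept", "diagnosis"]).mean()
    return CovariateModel(covariates=list(covariates), coef=coef,
                          centers=centers, training_ids=training_ids)


def apply_covariate_model(layer: OmicsLayer, model: CovariateModel,
                          meta: pd.DataFrame) -> OmicsLayer:
    """Subtract nuisance covariate effects using the training coefficients.

    Covariates are centered at their training means, so applying the model
    to the training data reproduces the in-sample partial residuals.
    """
    meta_s = meta.set_index("sample_id").loc[layer.sample_ids].reset_index()
    D = _design(meta_s, model.covariates)
    nuis = [c for c in D.columns if c not in ("intercept", "diagnosis")]
    Dn = D[nuis].to_numpy() - model.centers[nuis].to_numpy()[None, :]
    adj = layer.values.to_numpy(dtype=float) - model.coef[nuis].to_numpy() @ Dn.T
    out = pd.DataFrame(adj, index=layer.values.index, columns=layer.values.columns)
    return OmicsLayer(layer.layer, out, layer.presence)
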