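"""Repeated-split PLSR ensemble for case/control diagnosis.

The diagnostic is an ensemble of 15 PLS1 regressions (5 stratified folds x
3 repeats); each member is trained on 4/5 of the case/control cohort, its
component count tuned by inner 10-fold cross-validation on Cohen's kappa,
and evaluated on its held-out fifth.  The ensemble output is the
arithmetic mean of the 15 member predictions clipped to [0, 1] — the
"disease probability" — with a probability below 0.5 read as the
healthy-control side of the boundary (molecular remission when the sample
comes from a treated patient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsLayer
from .plsr import PLSRFit, fit_plsr

DEFAULT_GRID = tuple(range(1, 11))


# ------------------------------------------------------------------ splits

def repeated_split(sample_ids, labels, k: int = 5, repeats: int = 3, seed: int = 0):
    """Stratified k-fold split table, repeated with fresh shuffles.

    Returns a list of ``k * repeats`` dicts with keys ``train``/``test``
    (sample id lists) plus ``repeat``/``fold`` indices.
    """
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    splits = []
    for rep in range(repeats):
        fold_of = np.empty(len(sample_ids), dtype=int)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % k
        for fold in range(k):
            test = sample_ids[fold_of == fold]
            train = sample_ids[fold_of != fold]
            splits.append({"repeat": rep, "fold": fold,
                           "train": list(train), "test": list(test)})
    return splits


# ------------------------------------------------------------------- kappa

def cohen_kappa(pred_labels, true_labels) -> float:
    """Cohen's kappa, (p_o - p_e)/(1 - p_e); 0 when p_e = 1."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("label vectors must be nonempty and equal-length")
    n = pred.size
    classes = np.union1d(pred, true)
    p_o = float(np.mean(pred == true))
    p_e = sum(float(np.mean(pred == c)) * float(np.mean(true == c)) for c in classes)
    if p_e >= 1.0 - 1e-12:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


# -------------------------------------------------------- component choice

def _stratified_folds(labels, n_folds, rng):
    fold_of = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return fold_of


def select_ncomp(X, y, grid=DEFAULT_GRID, inner_folds: int = 10, seed: int = 0) -> int:
    """Pick the component count maximizing mean inner-CV Cohen's kappa.

    One nested PLS fit per inner fold covers the whole grid (PLS components
    are nested, so the s-component prediction is a prefix sum).  Ties and
    undefined kappas resolve toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    grid = sorted(set(int(g) for g in grid))
    if len(grid) == 1:
        return grid[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    fold_of = _stratified_folds(y, inner_folds, rng)
    kappas = {s: [] for s in grid}
    for fold in range(inner_folds):
        tr = fold_of != fold
        te = ~tr
        if te.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        lmax = min(max(grid), tr.sum() - 1, X.shape[1])
        try:
            fit = fit_plsr(X[tr], y[tr], lmax)
        except ValueError:
            fit = fit_plsr(X[tr], y[tr], 1)
        preds = fit.predict_components(X[te])      # n_test x lmax
        for s in grid:
            col = min(s, fit.n_components) - 1
            lab = (np.clip(preds[:, col], 0, 1) >= 0.5).astype(int)
            kappas[s].append(cohen_kappa(lab, y[te].astype(int)))
    mean_k = {s: (float(np.mean(v)) if v else 0.0) for s, v in kappas.items()}
    best = max(mean_k.values())
    return min(s for s in grid if mean_k[s] >= best - 1e-12)


# ---------------------------------------------------------------- ensemble

@dataclass
class EnsembleMember:
    fit: PLSRFit
    n_components: int
    train_ids: list
    test_ids: list
    test_accuracy: float


@dataclass
class EnsembleModel:
    """15 PLS1 members plus their split map; predicts disease probability."""

    members: list
    feature_ids: list
    k: int
    repeats: int
    seed: int
    label_map: dict = field(default_factory=lambda: {"HC": 0, "RA": 1})

    @property
    def heldout_accuracy(self) -> float:
        return float(np.mean([m.test_accuracy for m in self.members]))


def training_frame(layer: OmicsLayer, meta: pd.DataFrame):
    """Case/control training view: drug-naive patients plus controls."""
    meta_i = meta.set_index("sample_id").loc[layer.sample_ids]
    use = (meta_i["diagnosis"] == "HC") | ((meta_i["diagnosis"] == "RA")
                                           & (meta_i["arm"] == "none"))
    # bridge replicate columns (same biological sample re-assayed in another
    # batch) must not double-count as training samples
    use &= ~meta_i.index.str.contains(".br", regex=False)
    ids = list(meta_i.index[use])
    X = layer.values[ids].T          # samples x features
    y = (meta_i.loc[ids, "diagnosis"] == "RA").astype(int)
    return X, y


def fit_ensemble(layer: OmicsLayer, meta: pd.DataFrame, seed: int = 0,
                 k: int = 5, repeats: int = 3, grid=DEFAULT_GRID,
                 inner_folds: int = 10, labels=None) -> EnsembleModel:
    """Fit the k x repeats member ensemble on the naive case/control cohort.

    ``labels`` overrides the 0/1 outcome (used by the permutation null).
    """
    X, y = training_frame(layer, meta)
    if labels is not None:
        y = pd.Series(np.asarray(labels), index=y.index)
    splits = repeated_split(np.array(X.index), y.to_numpy(), k=k, repeats=repeats, seed=seed)
    members = []
    Xv = X.to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(X.index)}
    for j, sp in enumerate(splits):
        tr = [pos[s] for s in sp["train"]]
        te = [pos[s] for s in sp["test"]]
        ytr = y.to_numpy()[tr]
        ncomp = select_ncomp(Xv[tr], ytr, grid=grid, inner_folds=inner_folds,
                             seed=seed * 1000 + j)
        ncomp = min(ncomp, len(tr) - 1)
        fit = fit_plsr(Xv[tr], ytr, ncomp, training_ids=sp["train"],
                       feature_ids=list(X.columns))
        p_te = np.clip(fit.predict(Xv[te]), 0, 1)
        acc = float(np.mean((p_te >= 0.5).astype(int) == y.to_numpy()[te]))
        members.append(EnsembleMember(fit=fit, n_components=ncomp,
                                      train_ids=sp["train"], test_ids=sp["test"],
                                      test_accuracy=acc))
    return EnsembleModel(members=members, feature_ids=list(X.columns),
                         k=k, repeats=repeats, seed=seed)


def member_probabilities(model: EnsembleModel, X_new: pd.DataFrame) -> np.ndarray:
    """Clipped per-member probabilities, members x samples."""
    missing = [f for f in model.feature_ids if f not in X_new.index]
    if missing:
        raise ValueError(f"{len(missing)} model features missing from input")
    Xv = X_new.loc[model.feature_ids].T.to_numpy(dtype=float)
    return np.vstack([np.clip(m.fit.predict(Xv), 0, 1) for m in model.members])


def predict_probability(model: EnsembleModel, X_new: pd.DataFrame) -> pd.Series:
    """Ensemble disease probability: mean of the clipped member outputs."""
    probs = member_probabilities(model, X_new)
    return pd.Series(probs.mean(axis=0), index=X_new.columns, name="probability")


def to_log_odds(p, eps: float = 1e-6):
    """logit with clamping away from 0/1."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    out = np.log(p / (1 - p))
    return float(out) if out.ndim == 0 else out


def call_molecular_remission(p) -> bool:
    """True iff the model classifies the sample as control (p < 0.5)."""
    return bool(np.asarray(p, dtype=float) < 0.5)


def permutation_null(layer: OmicsLayer, meta: pd.DataFrame, n_perm: int,
                     seed: int = 0, **fit_kwargs):
    """Held-out accuracy distribution under diagnosis-label permutation.

    Each permutation shuffles the case/control labels and reruns the full
    ensemble fit, including inner component selection.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _, y = training_frame(layer, meta)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    accs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y.to_numpy())
        model = fit_ensemble(layer, meta, seed=seed * 9973 + i, labels=perm, **fit_kwargs)
        accs[i] = model.heldout_accuracy
    return {"accuracies": accs, "mean": float(accs.mean()),
            "sd": float(accs.std(ddof=1)) if n_perm > 1 else float("nan"),
            "se": float(accs.std(ddof=1) / math.sqrt(n_perm)) if n_perm > 1 else float("nan")}
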