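"""Plain-text (JSON) persistence for fitted ensemble models."""

from __future__ import annotations

import json

import numpy as np

from .ensemble import EnsembleMember, EnsembleModel
from .plsr import PLSRFit

_FIT_ARRAYS = ("x_mean", "x_sd", "weights", "loadings", "y_loadings",
               "scores", "rotations")


def save_ensemble(model: EnsembleModel, path) -> None:
    members = []
    for m in model.members:
        fit = {name: getattr(m.fit, name).tolist() for name in _FIT_ARRAYS}
        fit.update(n_components=m.fit.n_components, y_mean=m.fit.y_mean,
                   training_ids=m.fit.training_ids, feature_ids=[])
        members.append({"fit": fit, "n_components": m.n_components,
                        "train_ids": m.train_ids, "test_ids": m.test_ids,
                        "test_accuracy": m.test_accuracy})
    doc = {"format": "momira-ensemble-v1", "feature_ids": model.feature_ids,
           "k": model.k, "repeats": model.repeats, "seed": model.seed,
           "members": members}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ensemble(path) -> EnsembleModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "momira-ensemble-v1":
        raise ValueError("not a momira ensemble model file")
    members = []
    for m in doc["members"]:
        f = m["fit"]
        fit = PLSRFit(n_components=int(f["n_components"]),
                      x_mean=np.asarray(f["x_mean"]), x_sd=np.asarray(f["x_sd"]),
                      y_mean=float(f["y_mean"]),
                      weights=np.asarray(f["weights"]), loadings=np.asarray(f["loadings"]),
                      y_loadings=np.asarray(f["y_loadings"]), scores=np.asarray(f["scores"]),
                      rotations=np.asarray(f["rotations"]),
                      training_ids=f["training_ids"],
                      feature_ids=doc["feature_ids"])
        members.append(EnsembleMember(fit=fit, n_components=m["n_components"],
                                      train_ids=m["train_ids"], test_ids=m["test_ids"],
                                      test_accuracy=m["test_accuracy"]))
    return EnsembleModel(members=members, feature_ids=doc["feature_ids"],
                         k=doc["k"], repeats=doc["repeats"], seed=doc["seed"])
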