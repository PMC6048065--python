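"""Core in-memory containers shared across the pipeline.

An omics layer is a feature x sample matrix (pandas DataFrame) with a layer
tag and optional per-entry presence flags (detection calls).  Sample
metadata travels as a plain DataFrame with a fixed column schema, one row
per emitted sample column.  Signature sets are direction-tagged feature id
sets with provenance of the filters that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LAYER_TAGS = ("transcript", "protein", "cellcount")

#: required columns of a sample-metadata table, in canonical order
META_COLUMNS = (
    "sample_id",
    "subject_id",
    "diagnosis",   # RA | HC
    "arm",         # none | MTX | IFX | TCZ
    "week",
    "responder",   # bool; False also covers not-applicable (HC)
    "age",
    "gender",      # F | M
    "rin",
    "batch",
    "bridge",      # bool: subject assayed in both batches
)


@dataclass
class OmicsLayer:
    """One feature x sample measurement matrix.

    Parameters
    ----------
    layer:
        One of ``transcript``, ``protein``, ``cellcount``.
    values:
        DataFrame indexed by feature id, columns are sample ids.
    presence:
        Optional boolean DataFrame of identical shape (detection calls).
    """

    layer: str
    values: pd.DataFrame
    presence: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.layer not in LAYER_TAGS:
            raise ValueError(f"unknown layer tag {self.layer!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("non-finite values in layer matrix")
        if self.presence is not None:
            if self.presence.shape != self.values.shape:
                raise ValueError("presence flags must match matrix shape")
            self.presence = self.presence.astype(bool)
            self.presence.index = self.values.index
            self.presence.columns = self.values.columns

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "OmicsLayer":
        pres = self.presence[list(sample_ids)] if self.presence is not None else None
        return OmicsLayer(self.layer, self.values[list(sample_ids)].copy(), pres)

    def subset_features(self, feature_ids) -> "OmicsLayer":
        pres = self.presence.loc[list(feature_ids)] if self.presence is not None else None
        return OmicsLayer(self.layer, self.values.loc[list(feature_ids)].copy(), pres)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata schema and design-label invariants."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    hc = meta[meta["diagnosis"] == "HC"]
    if not ((hc["arm"] == "none").all() and (hc["week"] == 0).all()):
        raise ValueError("HC samples must have arm 'none' and week 0")
    key = meta[["subject_id", "week", "arm", "bridge"]]
    if key[~meta["bridge"]].duplicated(["subject_id", "week", "arm"]).any():
        raise ValueError("(subject_id, week, arm) not unique among non-bridge rows")
    return meta


@dataclass
class SignatureSet:
    """Direction-tagged feature sets with the provenance that produced them.

    ``stage`` distinguishes the baseline consensus disease signature from
    the post-treatment residual signature; ``provenance`` records thresholds
    and input descriptions for audit.
    """

    layer: str
    up: frozenset
    down: frozenset
    stage: str = "consensus"   # consensus | residual | custom
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if self.up & self.down:
            raise ValueError("up and down signature sets overlap")

    @property
    def all_features(self) -> frozenset:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)
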