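"""Readers/writers for the plain-text formats the pipeline exchanges.

Layers travel as TSV with a leading ``feature_id`` column; metadata as TSV
with the fixed schema of :data:`momira.datatypes.META_COLUMNS`; signatures
as GMT (one set per line: name, description, member ids).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import META_COLUMNS, OmicsLayer, SignatureSet, validate_meta


def write_layer(layer: OmicsLayer, path, presence_path=None) -> None:
    out = layer.values.copy()
    out.insert(0, "feature_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    if presence_path is not None and layer.presence is not None:
        pres = layer.presence.astype(int).copy()
        pres.insert(0, "feature_id", pres.index)
        pres.to_csv(presence_path, sep="\t", index=False)


def read_layer(path, layer_tag: str, presence_path=None) -> OmicsLayer:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("feature_id")
    df.index.name = None
    presence = None
    if presence_path is not None and Path(presence_path).exists():
        presence = pd.read_csv(presence_path, sep="\t").set_index("feature_id").astype(bool)
        presence.index.name = None
    return OmicsLayer(layer_tag, df, presence)


def write_meta(meta: pd.DataFrame, path) -> None:
    validate_meta(meta)[list(META_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    for col in ("responder", "bridge"):
        meta[col] = meta[col].astype(bool)
    return validate_meta(meta)


def write_gmt(signatures: list[SignatureSet], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            for direction in ("up", "down"):
                members = sorted(getattr(sig, direction))
                if not members:
                    continue
                name = f"{sig.layer}_{sig.stage}_{direction}"
                fh.write("\t".join([name, f"{direction} in RA"] + members) + "\n")


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file; tolerates a missing description field."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            name, rest = parts[0], parts[1:]
            # second column is a description unless it looks like the only member
            members = rest[1:] if len(rest) >= 2 else rest
            sets[name] = {m for m in members if m}
    return sets


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
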