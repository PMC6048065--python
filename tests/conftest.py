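import numpy as np
import pandas as pd
import pytest

from momira.datatypes import OmicsLayer
from momira.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort reused by unit tests (full-size runs live in the
    acceptance suite)."""
    cfg = CohortConfig(n_features=300, n_disease_features=30, n_rms_features=10, seed=11)
    layers, meta, truth = generate_cohort(cfg)
    return cfg, layers, meta, truth


@pytest.fixture()
def base_meta_factory():
    """Minimal valid metadata for hand-built toy layers."""

    def make(sample_ids, diagnosis=None, **overrides):
        n = len(sample_ids)
        meta = pd.DataFrame({
            "sample_id": sample_ids,
            "subject_id": [f"u{i}" for i in range(n)],
            "diagnosis": diagnosis if diagnosis is not None else ["HC"] * n,
            "arm": ["none"] * n,
            "week": [0] * n,
            "responder": [False] * n,
            "age": [50.0] * n,
            "gender": ["F"] * n,
            "rin": [8.0] * n,
            "batch": [1] * n,
            "bridge": [False] * n,
        })
        for key, val in overrides.items():
            meta[key] = val
        return meta

    return make


@pytest.fixture()
def toy_layer():
    def make(values, layer="transcript", presence=None, prefix="f", sample_prefix="s"):
        values = np.asarray(values, dtype=float)
        df = pd.DataFrame(values,
                          index=[f"{prefix}{i}" for i in range(values.shape[0])],
                          columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])])
        pres = None
        if presence is not None:
            pres = pd.DataFrame(np.asarray(presence, dtype=bool),
                                index=df.index, columns=df.columns)
        return OmicsLayer(layer, df, pres)

    return make
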