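"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the statistical structure of a two-batch case/control study of
rheumatoid arthritis with three longitudinal treatment arms: latent
immune-cell composition drives a share of every molecular layer
(neutrophil- and monocyte-like cells elevated, NK-like cells depressed in
disease), a planted subset of features carries a direct disease shift, and
a planted sub-subset of those is resistant to treatment (the ground-truth
residual molecular signature).  Age, RNA-integrity and batch act as
confounders; bridge subjects are assayed in both batches so the batch
model is estimable.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` substreams, so each ingredient (demographics,
cell abundances, loadings, noise, ...) is reproducible independently of
the others.

Generative model, per sample k and cell type c:

    log-abundance_ck ~ Normal(mu_c + delta_c * d_k * rem_k, sigma_c)

where ``d_k`` indicates disease and ``rem_k`` is the per-arm remaining
fraction of the disease effect at the sample's week (1 at week 0, decaying
under treatment).  Transcript/protein feature j:

    x_jk = base_j + sum_c L_jc z_ck + beta_age_j (age_k - 50)
           + beta_rin_j (rin_k - 8) + shift_j d_k rem'_jk + eps,

with ``z_ck`` the standardized log cell abundance, ``shift_j`` nonzero only
for planted disease features, and ``rem'_jk = 1`` for treatment-resistant
(RMS) features but ``rem_k`` otherwise.  Batch location/scale distortions
and measurement noise are applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import OmicsLayer, validate_meta

ARMS = ("MTX", "IFX", "TCZ")

#: remaining fraction of the disease effect by arm and week; biologics act
#: faster and deeper than methotrexate, mirroring the relative potency the
#: diagnostic models are meant to resolve
DEFAULT_DECAY = {
    "MTX": {0: 1.0, 4: 0.70, 24: 0.35},
    "IFX": {0: 1.0, 4: 0.45, 24: 0.12},
    "TCZ": {0: 1.0, 4: 0.40, 24: 0.08},
}

#: disease shift of each canonical cell type, in units of its own SD and
#: relative to a reference effect size of 2 SD (left shift: neutrophils and
#: monocytes up, NK cells down)
CELL_PATTERN = {"neutrophil": 1.0, "monocyte": 0.8, "nk": -0.8}

_BASE_CELLS = ("neutrophil", "monocyte", "nk", "cd4_t", "cd8_t", "b_cell")
_BASE_MU = {"neutrophil": 8.3, "monocyte": 6.0, "nk": 5.3,
            "cd4_t": 6.7, "cd8_t": 6.2, "b_cell": 5.5}


def cell_type_names(n_cell_types: int) -> list[str]:
    names = list(_BASE_CELLS[:n_cell_types])
    names += [f"celltype{i + 1}" for i in range(len(names), n_cell_types)]
    return names


@dataclass
class CohortConfig:
    """Study-design and effect-size knobs of the synthetic cohort."""

    n_ra_naive: int = 45
    n_hc: int = 35
    n_per_arm: int = 10
    weeks: tuple = (0, 4, 24)
    n_features: int = 2000            # per transcript/protein layer
    n_disease_features: int = 200
    n_rms_features: int = 50
    effect_size_sd_units: float = 2.0
    n_cell_types: int = 6
    batch_count: int = 2
    n_bridge_replicates: int = 8
    beta_age: float = 0.02            # per year, on age-responsive features
    beta_rin: float = 0.30            # per RIN unit, transcripts only
    cell_load_frac: float = 0.30      # fraction of background features with a cell loading
    noise_sd: float = 1.0
    batch_offset_sd: float = 0.4
    batch_scale_log_sd: float = 0.05
    treatment_decay: dict = field(default_factory=lambda: {a: dict(w) for a, w in
                                                           ((a, DEFAULT_DECAY[a].items()) for a in ARMS)})
    layers: tuple = ("transcript", "protein")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ra_naive", "n_hc", "n_per_arm", "n_features",
                     "n_cell_types", "batch_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.n_rms_features <= self.n_disease_features <= self.n_features):
            raise ValueError("need n_rms_features <= n_disease_features <= n_features")
        weeks = tuple(self.weeks)
        if list(weeks) != sorted(weeks) or 0 not in weeks:
            raise ValueError("weeks must be ascending and contain 0")
        self.weeks = weeks


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for downstream validation."""

    disease_features: dict            # layer -> {"up": [...], "down": [...]}
    rms_features: dict                # layer -> {"up": [...], "down": [...]}
    cell_loadings: dict               # layer -> DataFrame (feature x cell type)
    treatment_decay: dict             # arm -> {week: remaining fraction}
    cell_delta: pd.Series             # per-cell-type disease shift (SD units)

    def disease_ids(self, layer: str) -> frozenset:
        d = self.disease_features[layer]
        return frozenset(d["up"]) | frozenset(d["down"])

    def rms_ids(self, layer: str) -> frozenset:
        d = self.rms_features[layer]
        return frozenset(d["up"]) | frozenset(d["down"])


def _substreams(seed: int, names: list[str]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _build_meta(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_hc):
        rows.append(dict(sample_id=f"HC{i + 1:03d}", subject_id=f"hc{i + 1:03d}",
                         diagnosis="HC", arm="none", week=0, responder=False))
    for i in range(cfg.n_ra_naive):
        rows.append(dict(sample_id=f"RA{i + 1:03d}", subject_id=f"ra{i + 1:03d}",
                         diagnosis="RA", arm="none", week=0, responder=False))
    for arm in ARMS:
        for i in range(cfg.n_per_arm):
            subj = f"{arm.lower()}{i + 1:02d}"
            for w in cfg.weeks:
                rows.append(dict(sample_id=f"{arm}{i + 1:02d}_w{w:02d}",
                                 subject_id=subj, diagnosis="RA", arm=arm,
                                 week=w, responder=True))
    meta = pd.DataFrame(rows)

    subjects = meta.drop_duplicates("subject_id").set_index("subject_id")
    age = pd.Series(index=subjects.index, dtype=float)
    is_ra = subjects["diagnosis"] == "RA"
    age[is_ra] = np.clip(rng.normal(57, 11, is_ra.sum()), 22, 82)
    age[~is_ra] = np.clip(rng.normal(46, 12, (~is_ra).sum()), 22, 82)
    gender = pd.Series(np.where(rng.random(len(subjects)) < np.where(is_ra, 0.8, 0.6), "F", "M"),
                       index=subjects.index)
    batch = pd.Series(rng.integers(1, cfg.batch_count + 1, len(subjects)), index=subjects.index)

    meta["age"] = meta["subject_id"].map(age).round(1)
    meta["gender"] = meta["subject_id"].map(gender)
    meta["rin"] = np.clip(rng.normal(8.2, 0.6, len(meta)), 6.0, 10.0).round(2)
    meta["batch"] = meta["subject_id"].map(batch).astype(int)
    meta["bridge"] = False

    # bridge subjects: week-0 samples re-assayed in every other batch
    if cfg.batch_count > 1 and cfg.n_bridge_replicates > 0:
        wk0 = meta.index[(meta["week"] == 0) & (meta["arm"] == "none")]
        picks = rng.choice(wk0, size=min(cfg.n_bridge_replicates, len(wk0)), replace=False)
        meta.loc[picks, "bridge"] = True
        extra = []
        for idx in picks:
            row = meta.loc[idx].copy()
            others = [b for b in range(1, cfg.batch_count + 1) if b != row["batch"]]
            for b in others:
                rep = row.copy()
                rep["sample_id"] = f"{row['sample_id']}.br{b}"
                rep["batch"] = b
                extra.append(rep)
        meta = pd.concat([meta, pd.DataFrame(extra)], ignore_index=True)
    return validate_meta(meta.reset_index(drop=True))


def _cell_abundance(cfg, meta, rng):
    """Log cell abundances per unique biological sample (bridge copies share one draw)."""
    cells = cell_type_names(cfg.n_cell_types)
    mu = np.array([_BASE_MU.get(c, 5.8) for c in cells])
    sigma = np.full(len(cells), 0.30)
    delta = np.array([CELL_PATTERN.get(c, 0.0) for c in cells]) * (cfg.effect_size_sd_units / 2.0)

    base = meta[~meta["sample_id"].str.contains(".br", regex=False)]
    rem = _remaining_fraction(cfg, base)
    d = (base["diagnosis"] == "RA").to_numpy(float)
    logab = (mu[None, :]
             + (delta * sigma)[None, :] * (d * rem)[:, None]
             + rng.normal(0, 1, (len(base), len(cells))) * sigma[None, :])
    logab = pd.DataFrame(logab, index=base["sample_id"].to_numpy(), columns=cells)
    delta_s = pd.Series(delta, index=cells, name="delta_sd_units")
    return logab, delta_s, sigma


def _remaining_fraction(cfg, meta_rows) -> np.ndarray:
    rem = np.ones(len(meta_rows))
    arms = meta_rows["arm"].to_numpy()
    weeks = meta_rows["week"].to_numpy()
    for i, (a, w) in enumerate(zip(arms, weeks)):
        if a in cfg.treatment_decay:
            rem[i] = cfg.treatment_decay[a].get(int(w), 1.0)
    return rem


def _plant_features(cfg, layer_tag, rng):
    """Feature ids, disease shifts, RMS mask and cell loadings for one layer."""
    pref = {"transcript": "T", "protein": "P"}[layer_tag]
    ids = np.array([f"{pref}{j + 1:05d}" for j in range(cfg.n_features)])
    order = rng.permutation(cfg.n_features)
    disease_idx = order[:cfg.n_disease_features]
    rms_idx = disease_idx[:cfg.n_rms_features]

    sign = np.zeros(cfg.n_features)
    sign[disease_idx] = np.where(rng.random(cfg.n_disease_features) < 0.5, 1.0, -1.0)

    cells = cell_type_names(cfg.n_cell_types)
    L = np.zeros((cfg.n_features, len(cells)))
    # background features: sparse single-cell loadings
    bg = rng.random(cfg.n_features) < cfg.cell_load_frac
    which = rng.integers(0, len(cells), cfg.n_features)
    L[np.arange(cfg.n_features), which] = np.where(bg, rng.normal(0, 0.4, cfg.n_features), 0.0)
    # treatment-resistant features additionally load on the driver cells, with
    # the sign matched to their disease direction (left-shift biology)
    driver = {c: CELL_PATTERN[c] for c in CELL_PATTERN if c in cells}
    for c, pat in driver.items():
        ci = cells.index(c)
        L[rms_idx, ci] = sign[rms_idx] * np.sign(pat) * rng.uniform(0.4, 0.8, len(rms_idx))

    # disease shift in units of each feature's marginal SD (noise plus
    # cell-mediated variance), so the planted standardized effect is the
    # configured size regardless of how strongly the feature tracks cells
    marginal_sd = np.sqrt(cfg.noise_sd ** 2 + (L ** 2).sum(axis=1))
    mag = cfg.effect_size_sd_units * rng.uniform(0.9, 1.2, cfg.n_features)
    shift = sign * mag * marginal_sd

    rms_mask = np.zeros(cfg.n_features, bool)
    rms_mask[rms_idx] = True
    dis_mask = np.zeros(cfg.n_features, bool)
    dis_mask[disease_idx] = True
    return ids, shift, dis_mask, rms_mask, pd.DataFrame(L, index=ids, columns=cells)


def _emit_layer(cfg, layer_tag, meta, z_cells, rng):
    ids, shift, dis_mask, rms_mask, L = _plant_features(cfg, layer_tag, rng)
    m = cfg.n_features

    base = rng.normal(7.0, 2.0, m)
    age_on = rng.random(m) < 0.5
    beta_age = np.where(age_on, rng.normal(cfg.beta_age, cfg.beta_age / 2, m), 0.0)
    if layer_tag == "transcript":
        rin_on = rng.random(m) < 0.5
        beta_rin = np.where(rin_on, rng.normal(cfg.beta_rin, cfg.beta_rin / 2, m), 0.0)
    else:
        beta_rin = np.zeros(m)
    boff = np.zeros((m, cfg.batch_count + 1))
    bscale = np.ones((m, cfg.batch_count + 1))
    for b in range(2, cfg.batch_count + 1):
        boff[:, b] = rng.normal(0, cfg.batch_offset_sd, m)
        bscale[:, b] = np.exp(rng.normal(0, cfg.batch_scale_log_sd, m))

    base_sample = meta["sample_id"].str.replace(r"\.br\d+$", "", regex=True)
    Z = z_cells.loc[base_sample].to_numpy()              # emitted-sample x cell
    rem = _remaining_fraction(cfg, meta)
    d = (meta["diagnosis"] == "RA").to_numpy(float)
    rem_feat = np.where(rms_mask[:, None], 1.0, rem[None, :])      # m x n
    clean = (base[:, None]
             + L.to_numpy() @ Z.T
             + beta_age[:, None] * (meta["age"].to_numpy() - 50.0)[None, :]
             + beta_rin[:, None] * (meta["rin"].to_numpy() - 8.0)[None, :]
             + shift[:, None] * d[None, :] * rem_feat)
    bcols = meta["batch"].to_numpy()
    noisy = clean + rng.normal(0, cfg.noise_sd, clean.shape)
    X = noisy * bscale[:, bcols] + boff[:, bcols]

    values = pd.DataFrame(X, index=ids, columns=meta["sample_id"].to_numpy())
    presence = None
    if layer_tag == "transcript":
        p = expit((base - 3.5) / 0.8)
        presence = pd.DataFrame(rng.random(values.shape) < p[:, None],
                                index=ids, columns=values.columns)
    truth_bits = dict(
        disease={"up": sorted(ids[dis_mask & (shift > 0)]),
                 "down": sorted(ids[dis_mask & (shift < 0)])},
        rms={"up": sorted(ids[rms_mask & (shift > 0)]),
             "down": sorted(ids[rms_mask & (shift < 0)])},
        loadings=L,
    )
    return OmicsLayer(layer_tag, values, presence), truth_bits


def _emit_cellcount_layer(cfg, meta, logab):
    base_sample = meta["sample_id"].str.replace(r"\.br\d+$", "", regex=True)
    ab = np.exp(logab.loc[base_sample].to_numpy())       # n x c, absolute counts
    rel = ab / ab.sum(axis=1, keepdims=True)
    cells = list(logab.columns)
    rows, names = [], []
    for i, c in enumerate(cells):
        names += [f"{c}_a", f"{c}_r"]
        rows += [ab[:, i], rel[:, i]]
    values = pd.DataFrame(np.array(rows), index=names, columns=meta["sample_id"].to_numpy())
    return OmicsLayer("cellcount", values)


def generate_cohort(config: CohortConfig):
    """Generate the synthetic cohort.

    Returns
    -------
    layers : dict of layer tag -> OmicsLayer
        Requested transcript/protein layers plus a ``cellcount`` layer.
    meta : DataFrame
        One row per emitted sample column (bridge replicates included,
        suffixed ``.br<batch>``).
    truth : SyntheticTruth
    """
    cfg = config
    rngs = _substreams(cfg.seed, ["meta", "cells", "transcript", "protein"])
    meta = _build_meta(cfg, rngs["meta"])
    logab, delta_s, sigma = _cell_abundance(cfg, meta, rngs["cells"])
    z_cells = (logab - logab.mean()) / logab.std(ddof=0)

    layers = {}
    disease, rms, loadings = {}, {}, {}
    for tag in cfg.layers:
        layer, bits = _emit_layer(cfg, tag, meta, z_cells, rngs[tag])
        layers[tag] = layer
        disease[tag] = bits["disease"]
        rms[tag] = bits["rms"]
        loadings[tag] = bits["loadings"]
    layers["cellcount"] = _emit_cellcount_layer(cfg, meta, logab)

    truth = SyntheticTruth(disease_features=disease, rms_features=rms,
                           cell_loadings=loadings,
                           treatment_decay={a: dict(v) for a, v in cfg.treatment_decay.items()},
                           cell_delta=delta_s)
    return layers, meta, truth


def generate_reference_profiles(n_cell_types: int, feature_ids, truth: SyntheticTruth,
                                seed: int, layer: str = "transcript") -> OmicsLayer:
    """Reference expression profiles of purified immune cells.

    One column per cell type; a feature loaded on cell type ``c`` in the
    cohort's ground truth has proportionally elevated (or depressed) signal
    in column ``c``.
    """
    L = truth.cell_loadings[layer]
    feature_ids = list(feature_ids)
    missing = set(feature_ids) - set(L.index)
    if missing:
        raise ValueError(f"{len(missing)} feature ids absent from truth loadings")
    cells = cell_type_names(n_cell_types)
    if list(L.columns) != cells:
        raise ValueError("n_cell_types inconsistent with truth loadings")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2 ** 20]))
    base = rng.normal(6.0, 1.0, len(feature_ids))
    prof = base[:, None] + 2.5 * L.loc[feature_ids].to_numpy() + rng.normal(0, 0.2, (len(feature_ids), len(cells)))
    return OmicsLayer(layer, pd.DataFrame(prof, index=feature_ids, columns=cells))
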