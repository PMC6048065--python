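"""Residual molecular signatures: consensus-then-persistence calling.

Stage 1 (consensus): features significantly deviant from healthy controls
at treatment start, in the same direction, in *all three* treatment arms
(p < 0.05 and q < 0.05 in each).  Stage 2 (residual): the subset of the
consensus that is still significantly deviant in the unchanged direction
in all arms after 24 weeks of treatment — the treatment-resistant core of
the disease signature.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import SignatureSet

ARMS = ("MTX", "IFX", "TCZ")


def _check_universe(tables: dict) -> list:
    universes = {arm: list(t["feature_id"]) for arm, t in tables.items()}
    first = next(iter(universes.values()))
    for arm, u in universes.items():
        if set(u) != set(first):
            raise ValueError(f"feature universe of arm {arm} differs")
    return first


def _gated_direction(table: pd.DataFrame, p_max: float, q_max: float) -> pd.Series:
    """Per feature: signed direction if the p&q gate passes, else 0."""
    t = table.set_index("feature_id")
    passed = (t["p"] < p_max) & (t["q"] < q_max)
    return t["direction"].where(passed, 0).astype(int)


def consensus_signature(de_by_arm: dict, p_max: float = 0.05, q_max: float = 0.05,
                        layer: str = "transcript") -> SignatureSet:
    """Baseline consensus disease signature across treatment arms.

    ``de_by_arm`` maps arm name -> DE table (each arm's week-0 responders
    vs controls) over a shared feature universe.
    """
    universe = _check_universe(de_by_arm)
    dirs = pd.DataFrame({arm: _gated_direction(t, p_max, q_max)
                         for arm, t in de_by_arm.items()}).loc[universe]
    up = dirs.index[(dirs == 1).all(axis=1)]
    down = dirs.index[(dirs == -1).all(axis=1)]
    return SignatureSet(layer=layer, up=frozenset(up), down=frozenset(down),
                        stage="consensus",
                        provenance={"p_max": p_max, "q_max": q_max,
                                    "arms": sorted(de_by_arm)})


def residual_signature(consensus: SignatureSet, de24_by_arm: dict,
                       p_max: float = 0.05, q_max: float = 0.05) -> SignatureSet:
    """Consensus features still deviant in the same direction at week 24."""
    universe = set(_check_universe(de24_by_arm))
    if not (consensus.up | consensus.down) <= universe and len(consensus):
        raise ValueError("consensus features missing from week-24 universe")
    dirs = pd.DataFrame({arm: _gated_direction(t, p_max, q_max)
                         for arm, t in de24_by_arm.items()})
    up = [f for f in consensus.up if (dirs.loc[f] == 1).all()]
    down = [f for f in consensus.down if (dirs.loc[f] == -1).all()]
    return SignatureSet(layer=consensus.layer, up=frozenset(up), down=frozenset(down),
                        stage="residual",
                        provenance={"p_max": p_max, "q_max": q_max,
                                    "arms": sorted(de24_by_arm),
                                    "consensus_size": len(consensus)})


def arm_specific_residuals(consensus: SignatureSet, de24_by_arm: dict,
                           p_max: float = 0.05, q_max: float = 0.05) -> dict:
    """Per-arm residual signatures (the Venn view across treatments)."""
    out = {}
    for arm, table in de24_by_arm.items():
        out[arm] = residual_signature(consensus, {arm: table}, p_max=p_max, q_max=q_max)
    return out
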