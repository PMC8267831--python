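"""Marker-gene phenotype prediction and family-level trait contrasts.

Pathway rules operate on detected marker counts only:
demethylation needs one copy each of dmdA/dmdB/dmdC; cleavage needs any
of the six lyase genes; AHL quorum sensing needs at least one luxI and
one luxR.  High salinity is inclusive at exactly 3.5% NaCl.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import pandas as pd

from .model import DDD_GENES, DMD_GENES, StrainRecord
from .stats import two_proportion_z

TRAIT_NAMES = ("dmsp_demethylation", "dmsp_cleavage", "ahl_qs",
               "high_salinity")


@dataclass
class TraitProfile:
    strain_id: str
    dmsp_demethylation: bool
    dmsp_cleavage: bool
    ahl_qs: bool
    high_salinity: Optional[bool]
    environment: str


def call_pathways(record: StrainRecord,
                  nacl_high: float = 3.5) -> TraitProfile:
    counts = record.marker_counts()
    demeth = all(counts.get(g, 0) >= 1 for g in DMD_GENES)
    cleave = any(counts.get(g, 0) >= 1 for g in DDD_GENES)
    qs = counts.get("luxI", 0) >= 1 and counts.get("luxR", 0) >= 1
    high_salt = (None if record.nacl_percent is None
                 else record.nacl_percent >= nacl_high)
    return TraitProfile(
        strain_id=record.strain_id,
        dmsp_demethylation=demeth,
        dmsp_cleavage=cleave,
        ahl_qs=qs,
        high_salinity=high_salt,
        environment=record.environment,
    )


def profiles_table(profiles: list[TraitProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "strain_id": p.strain_id,
        "dmsp_demethylation": p.dmsp_demethylation,
        "dmsp_cleavage": p.dmsp_cleavage,
        "ahl_qs": p.ahl_qs,
        "high_salinity": p.high_salinity,
        "environment": p.environment,
    } for p in profiles])


def family_trait_contrast(profiles: list[TraitProfile],
                          family_of: dict[str, str],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-trait proportions, z tests, and combination frequencies.

    Returns one row per trait and per trait combination (joined with
    '+'); combination rows include the both-DMSP-pathways fraction.
    """
    families = sorted(set(family_of.values()))
    if len(families) != 2:
        raise ValueError(f"need exactly two families, got {families}")
    fam_a, fam_b = families
    grouped: dict[str, list[TraitProfile]] = {fam_a: [], fam_b: []}
    for p in profiles:
        fam = family_of.get(p.strain_id)
        if fam in grouped:
            grouped[fam].append(p)
    for fam in families:
        if not grouped[fam]:
            raise ValueError(f"family {fam!r} has no profiles")

    def positive(profile: TraitProfile, trait: str) -> bool:
        return bool(getattr(profile, trait))

    rows = []

    def add_row(name: str, traits: tuple[str, ...]) -> None:
        counts = {}
        ns = {}
        for fam in families:
            members = grouped[fam]
            if "high_salinity" in traits:
                members = [p for p in members if p.high_salinity is not None]
            ns[fam] = len(members)
            counts[fam] = sum(
                1 for p in members if all(positive(p, t) for t in traits))
        if min(ns.values()) == 0:
            return
        z, p_val = two_proportion_z(counts[fam_a], ns[fam_a],
                                    counts[fam_b], ns[fam_b])
        prop_a = counts[fam_a] / ns[fam_a]
        prop_b = counts[fam_b] / ns[fam_b]
        rows.append({
            "trait": name,
            f"proportion_{fam_a}": prop_a,
            f"proportion_{fam_b}": prop_b,
            "difference": prop_a - prop_b,
            "z": z,
            "p": p_val,
            "significant": p_val < alpha,
        })

    for trait in TRAIT_NAMES:
        add_row(trait, (trait,))
    for pair in combinations(TRAIT_NAMES, 2):
        add_row("+".join(pair), pair)
    return pd.DataFrame(rows)


def trait_indicator_summary(contrast: pd.DataFrame,
                            top_n: int = 3) -> list[dict]:
    """Traits ranked by absolute proportion difference between families."""
    ranked = contrast.copy()
    ranked["abs_difference"] = ranked["difference"].abs()
    ranked = ranked[ranked["abs_difference"] > 0]
    ranked = ranked.sort_values(
        ["abs_difference", "trait"], ascending=[False, True])
    out = []
    for i, (_, row) in enumerate(ranked.iterrows()):
        out.append({
            "trait": row["trait"],
            "abs_difference": float(row["abs_difference"]),
            "indicator": i < top_n,
        })
    return out
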