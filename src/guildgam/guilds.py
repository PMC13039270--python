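"""Feeding-guild vocabulary and taxonomic guild assignment.

Insect taxa are resolved into six feeding guilds spanning three trophic
layers: phytophages, predators and saprophages, each with an associated
parasitoid guild.  Assignment works by taxonomic-group lookup in a trait
table — subfamily entries take precedence over family entries, mirroring the
practice of grouping the three most species-rich families (Ichneumonidae,
Braconidae, Staphylinidae) at subfamily level and everything else at family
level.  Every species in a group is assumed to belong to the group's
dominant guild.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GUILDS", "HOSTS", "PARASITOID_OF", "TraitTableError", "assign_guilds"]

#: the closed six-label guild set
GUILDS = (
    "phytophage",
    "predator",
    "saprophage",
    "phytophage_parasitoid",
    "predator_parasitoid",
    "saprophage_parasitoid",
)

#: host guilds, in canonical order
HOSTS = ("phytophage", "predator", "saprophage")

#: host guild -> its parasitoid guild
PARASITOID_OF = {h: f"{h}_parasitoid" for h in HOSTS}


class TraitTableError(ValueError):
    """Malformed trait table (duplicate groups, unknown guild labels...)."""


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    for col in ("taxon_group", "guild"):
        if col not in traits:
            raise TraitTableError(f"trait table lacks required column {col!r}")
    dup = traits["taxon_group"][traits["taxon_group"].duplicated()]
    if len(dup):
        raise TraitTableError(
            f"duplicate taxon_group entries: {sorted(dup.unique())}"
        )
    bad = set(traits["guild"]) - set(GUILDS)
    if bad:
        raise TraitTableError(
            f"guild labels outside the six-guild set: {sorted(bad)}"
        )
    return traits


def assign_guilds(otus: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Annotate an OTU table with feeding guilds.

    Parameters
    ----------
    otus
        One row per OTU (or per OTU occurrence); must carry ``family`` and
        may carry ``subfamily``.
    traits
        Columns ``taxon_group`` (unique) and ``guild``.

    Returns
    -------
    A copy of ``otus`` with a ``guild`` column; OTUs whose subfamily and
    family are both absent from the trait table get ``guild = NaN`` and
    ``unassigned = True``.  Subfamily matches take precedence over family
    matches.
    """
    validate_trait_table(traits)
    if "family" not in otus:
        raise ValueError("OTU table lacks required column 'family'")
    lut = dict(zip(traits["taxon_group"], traits["guild"]))
    out = otus.copy()
    fam_guild = out["family"].map(lut)
    if "subfamily" in out:
        sub_guild = out["subfamily"].map(lut)
        guild = sub_guild.fillna(fam_guild)
    else:
        guild = fam_guild
    out["guild"] = guild
    out["unassigned"] = guild.isna()
    n_un = int(out["unassigned"].sum())
    if n_un:
        logger.warning(
            "%d of %d OTU rows could not be assigned a guild and are "
            "excluded from richness", n_un, len(out),
        )
    return out
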