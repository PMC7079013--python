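"""Two-step identification update for delimited species and training labels.

Step one propagates collection-based morphological species identifications
across each species-group: a group with at least one specimen identified to
species level gives that name to every member.  Step two names the groups
still lacking species-level identifications from their best reference-
library match, with the customary percent-identity ladder: >=97% with a
species-named hit -> species name; >=90 and <97% -> genus name; >=80 and
<90% -> family name; anything else falls back to "<Order> sp.".

Finally, species-rank names are looked up in the biogeographic checklist to
assign training statuses; only endemic or introduced species enter the
model's training set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .delimit import SpeciesPartition
from .records import Checklist, SpecimenRecord, TopHit

log = logging.getLogger(__name__)


@dataclass
class SpeciesIdentity:
    species_id: str
    assigned_name: Optional[str]
    assigned_rank: str  # species | genus | family | order | none
    source: str  # morphology | reference-match | fallback | none


def _groups(partition: SpeciesPartition) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sid, gid in partition.assignment.items():
        groups.setdefault(gid, []).append(sid)
    return groups


def propagate_morphology(
    partition: SpeciesPartition, records: list[SpecimenRecord]
) -> dict[str, SpeciesIdentity]:
    """Step one: spread morphological species-level names within groups.

    Conflicting names inside a group resolve to the most frequent name
    (ties to lexicographic order) and the conflict is logged.
    """
    by_id = {r.specimen_id: r for r in records}
    identities: dict[str, SpeciesIdentity] = {}
    for gid, members in sorted(_groups(partition).items()):
        names = [
            by_id[m].morph_species
            for m in members
            if m in by_id
            and by_id[m].morph_rank == "species"
            and by_id[m].morph_species
        ]
        if not names:
            identities[gid] = SpeciesIdentity(gid, None, "none", "none")
            continue
        counts = Counter(names)
        if len(counts) > 1:
            log.warning(
                "species-group %s has conflicting morphological names %s",
                gid,
                dict(counts),
            )
        top = max(counts.values())
        name = min(n for n, c in counts.items() if c == top)
        identities[gid] = SpeciesIdentity(gid, name, "species", "morphology")
    return identities


def best_tophit(records: list[SpecimenRecord]) -> Optional[TopHit]:
    """Best reference match among a group's specimens: maximum percent
    identity, ties broken toward the more specific hit rank."""
    rank_order = {"species": 0, "genus": 1, "family": 2, "order": 3, "none": 4}
    hits = [r.tophit for r in records if r.tophit is not None]
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.identity, rank_order[h.rank()]))


def propagate_reference_match(
    identities: dict[str, SpeciesIdentity],
    partition: SpeciesPartition,
    records: list[SpecimenRecord],
) -> dict[str, SpeciesIdentity]:
    """Step two: name the still-unnamed groups from reference matches.

    Thresholds are half-open exactly as customary: [97, 100] species-level,
    [90, 97) genus, [80, 90) family, below 80 the order-level fallback
    "<Order> sp.".  Never demotes an existing species-level name.
    """
    by_id = {r.specimen_id: r for r in records}
    order_of = {
        gid: next(
            (by_id[m].order for m in members if m in by_id), ""
        )
        for gid, members in _groups(partition).items()
    }
    out = dict(identities)
    for gid, members in sorted(_groups(partition).items()):
        current = out.get(gid)
        if current is not None and current.assigned_rank == "species":
            continue
        recs = [by_id[m] for m in members if m in by_id]
        hit = best_tophit(recs)
        name, rank, source = None, "none", "none"
        if hit is not None:
            pid = hit.identity
            if pid >= 97 and hit.species:
                name, rank, source = hit.species, "species", "reference-match"
            elif pid >= 90 and (hit.species or hit.genus):
                genus = hit.genus or hit.species.split()[0]
                name, rank, source = genus, "genus", "reference-match"
            elif 80 <= pid < 90 and (hit.species or hit.genus or hit.family):
                family = hit.family or hit.genus or (
                    hit.species.split()[0] if hit.species else None
                )
                if family:
                    name, rank, source = family, "family", "reference-match"
        if name is None:
            name, rank, source = f"{order_of[gid]} sp.", "order", "fallback"
        out[gid] = SpeciesIdentity(gid, name, rank, source)
    return out


def assign_training_status(
    identities: dict[str, SpeciesIdentity], checklist: Checklist
) -> dict[str, str]:
    """Checklist status for every species-group.

    Only groups carrying a species-rank name can match the checklist; all
    others are "unknown".
    """
    statuses: dict[str, str] = {}
    for gid, ident in identities.items():
        if ident.assigned_rank == "species" and ident.assigned_name:
            statuses[gid] = checklist.status(ident.assigned_name)
        else:
            statuses[gid] = "unknown"
    return statuses
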