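"""Core record types shared across the pipeline.

A :class:`SpecimenRecord` carries one COI barcode sequence together with the
morphological identification made in the field and, when available, the
summary of its best match against a public reference library (a "top hit").
Aligned sequences for one arthropod order are held in an
:class:`OrderAlignment`; the biogeographic checklist that supplies training
labels is a :class:`Checklist`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MORPH_RANKS = ("species", "genus", "family", "order", "none")
STATUSES = ("endemic", "introduced", "unknown")

#: IUPAC nucleotide codes accepted in input sequences (plus '-' for gaps).
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")


@dataclass
class TopHit:
    """Best reference-library match for a specimen."""

    identity: float  # percent identity in [0, 100]
    species: Optional[str] = None
    genus: Optional[str] = None
    family: Optional[str] = None
    order: Optional[str] = None

    def rank(self) -> str:
        """Most specific taxonomic rank named by the hit."""
        if self.species:
            return "species"
        if self.genus:
            return "genus"
        if self.family:
            return "family"
        if self.order:
            return "order"
        return "none"


@dataclass
class SpecimenRecord:
    specimen_id: str
    order: str
    sequence: str
    morph_species: Optional[str] = None
    morph_rank: str = "none"
    tophit: Optional[TopHit] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.specimen_id}: empty sequence")
        if not self.order:
            raise ValueError(f"{self.specimen_id}: empty order")
        if self.morph_rank not in MORPH_RANKS:
            raise ValueError(f"{self.specimen_id}: bad morph_rank {self.morph_rank!r}")
        self.sequence = self.sequence.upper()

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


@dataclass
class OrderAlignment:
    """Aligned barcode sequences for one order.

    Rows are stored both as strings (``seqs``) and as a byte matrix for
    vectorized column arithmetic.
    """

    order: str
    ids: list[str]
    seqs: list[str]
    matrix: np.ndarray = field(repr=False, default=None)  # (n, columns) dtype 'S1'

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dup}")
        if self.seqs:
            lengths = {len(s) for s in self.seqs}
            if len(lengths) > 1:
                raise ValueError(
                    f"alignment rows have unequal lengths {sorted(lengths)}"
                )
        self.seqs = [s.upper() for s in self.seqs]
        if self.matrix is None:
            self.matrix = _to_matrix(self.seqs)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def subset(self, keep_ids: list[str]) -> "OrderAlignment":
        keep = set(keep_ids)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep]
        return OrderAlignment(
            order=self.order,
            ids=[self.ids[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
        )


def _to_matrix(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), dtype="S1")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").reshape(
        len(seqs), len(seqs[0])
    )


@dataclass
class Checklist:
    """Species name -> biogeographic status (endemic / introduced / unknown).

    Names are normalized to lower case with collapsed whitespace so that
    checklist lookups tolerate formatting differences.
    """

    entries: dict[str, str]

    @staticmethod
    def normalize(name: str) -> str:
        return " ".join(name.split()).lower()

    def status(self, name: Optional[str]) -> str:
        if not name:
            return "unknown"
        return self.entries.get(self.normalize(name), "unknown")


@dataclass
class SpeciesStats:
    """Per-species nucleotide-diversity statistics feeding the model.

    ``avg_within`` is the mean pairwise distance among the species' own
    specimens (the field's "average similarity", despite the name a
    distance); it is None for singleton species.  ``nn_distance`` is the
    mean-linkage distance to the nearest-neighbor species in the same order,
    None when the order holds a single species.
    """

    species_id: str
    order: str
    n_specimens: int
    avg_within: Optional[float]
    nn_distance: Optional[float]
    training_status: str = "unknown"
    glmm_score: Optional[float] = None
    category: Optional[str] = None
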