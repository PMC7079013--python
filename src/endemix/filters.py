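"""Quality-control filters applied to barcode data before analysis.

Three filters, in pipeline order:

1. minimum ungapped length (default 300 bp) — short barcodes cannot give
   reliable pairwise distance estimates;
2. contaminant screen — a specimen whose best reference-library match
   belongs to a different order than its morphological identification is
   treated as a cross-contamination and removed;
3. minimum pairwise overlap within each order alignment (default strictly
   more than 100 shared informative columns for every pair) — pairwise
   deletion needs enough shared sites for every retained pair.

Every filter partitions its input into (kept, removed); applying a filter
twice is a no-op on the kept part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import OrderAlignment, SpecimenRecord

log = logging.getLogger(__name__)


@dataclass
class RemovedRecord:
    specimen_id: str
    reason: str


def filter_min_length(
    records: list[SpecimenRecord], min_bp: int = 300
) -> tuple[list[SpecimenRecord], list[RemovedRecord]]:
    """Drop records whose ungapped sequence length is below ``min_bp``."""
    kept, removed = [], []
    for rec in records:
        if rec.ungapped_length >= min_bp:
            kept.append(rec)
        else:
            removed.append(RemovedRecord(rec.specimen_id, "short"))
    return kept, removed


def filter_contaminants(
    records: list[SpecimenRecord],
) -> tuple[list[SpecimenRecord], list[RemovedRecord]]:
    """Drop records whose top-hit order disagrees with the morphological order.

    Records without a top hit (or whose hit names no order) are kept: only a
    demonstrated order-level mismatch is evidence of contamination.
    """
    kept, removed = [], []
    for rec in records:
        hit_order = rec.tophit.order if rec.tophit else None
        if hit_order and hit_order.strip().lower() != rec.order.strip().lower():
            removed.append(RemovedRecord(rec.specimen_id, "contaminant"))
        else:
            kept.append(rec)
    return kept, removed


def pairwise_overlap(aln: OrderAlignment) -> np.ndarray:
    """Count, for every pair of rows, columns where BOTH rows carry a
    non-gap, non-'N' character ('N' carries no comparable information)."""
    m = aln.matrix
    informative = (m != b"-") & (m != b"N")
    return informative.astype(np.int32) @ informative.T.astype(np.int32)


def filter_min_overlap(
    aln: OrderAlignment, min_overlap: int = 100
) -> tuple[OrderAlignment, list[str]]:
    """Greedily remove sequences until every remaining pair shares strictly
    more than ``min_overlap`` informative columns.

    At each step the sequence in the most violating pairs is dropped; ties
    go to the shorter ungapped sequence, then to the lexicographically
    larger id.  Deterministic for a given alignment.
    """
    if aln.n == 0:
        return aln, []
    overlap = pairwise_overlap(aln)
    informative_len = np.diag(overlap).copy()
    active = np.ones(aln.n, dtype=bool)
    removed: list[str] = []

    while True:
        sub = np.where(active)[0]
        if len(sub) < 2:
            break
        viol = overlap[np.ix_(sub, sub)] <= min_overlap
        np.fill_diagonal(viol, False)
        counts = viol.sum(axis=1)
        if counts.max() == 0:
            break
        # worst offender; ties -> shorter sequence -> lexicographically larger id
        candidates = sub[counts == counts.max()]
        lengths = informative_len[candidates]
        candidates = candidates[lengths == lengths.min()]
        drop = max(candidates, key=lambda i: aln.ids[i])
        active[drop] = False
        removed.append(aln.ids[drop])

    if removed:
        keep_ids = [aln.ids[i] for i in np.where(active)[0]]
        if len(keep_ids) <= 1:
            log.warning(
                "overlap filter left %d sequence(s) in %s", len(keep_ids), aln.order
            )
        return aln.subset(keep_ids), removed
    return aln, removed
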