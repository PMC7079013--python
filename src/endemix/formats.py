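"""Readers and writers for the pipeline's external file formats.

All tabular formats are RFC-4180 CSV (TSV for the blast-style top-hit
table) with mandatory header rows:

* ``metadata.csv`` — specimen_id, order, morph_rank, morph_name
* ``tophits.tsv`` — query_id, pct_identity, hit_species, hit_genus,
  hit_family, hit_order (empty fields allowed)
* ``checklist.csv`` — species_name, status
* ``species_summary.csv`` — one row per delimited species with its
  statistics, training status, model score and category

Alignments are standard FASTA with ``-`` gaps, one file per order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Checklist, OrderAlignment, SpeciesStats, TopHit, STATUSES

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A tabular input is missing a mandatory column."""


class AlignmentFormatError(ValueError):
    """A FASTA alignment violates the equal-length / unique-id contract."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_alignment(path, order: str) -> OrderAlignment:
    """Read an aligned FASTA file into an :class:`OrderAlignment`.

    Rows keep file order; lowercase bases are normalized to uppercase.
    Unequal row lengths or duplicate ids raise :class:`AlignmentFormatError`.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    try:
        return OrderAlignment(order=order, ids=ids, seqs=seqs)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc


def write_alignment(aln: OrderAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, ["specimen_id", "order", "morph_rank", "morph_name"], path)
    return df


def read_tophits(path) -> dict[str, TopHit]:
    """Read the blast-style top-hit TSV into a mapping query_id -> TopHit."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(
        df,
        ["query_id", "pct_identity", "hit_species", "hit_genus", "hit_family", "hit_order"],
        path,
    )
    hits: dict[str, TopHit] = {}
    for row in df.itertuples(index=False):
        if row.pct_identity == "":
            continue
        hits[row.query_id] = TopHit(
            identity=float(row.pct_identity),
            species=row.hit_species or None,
            genus=row.hit_genus or None,
            family=row.hit_family or None,
            order=row.hit_order or None,
        )
    return hits


def read_checklist(path) -> Checklist:
    """Read checklist.csv; statuses outside the known vocabulary map to
    ``unknown`` with a logged warning."""
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, ["species_name", "status"], path)
    entries: dict[str, str] = {}
    for row in df.itertuples(index=False):
        status = row.status.strip().lower()
        if status not in STATUSES:
            log.warning(
                "checklist: status %r for %r is not endemic/introduced/unknown; "
                "treating as unknown",
                row.status,
                row.species_name,
            )
            status = "unknown"
        entries[Checklist.normalize(row.species_name)] = status
    return Checklist(entries=entries)


SUMMARY_COLUMNS = [
    "species_id",
    "order",
    "n_specimens",
    "avg_within",
    "nn_distance",
    "training_status",
    "glmm_score",
    "category",
]


def write_species_summary(stats: list[SpeciesStats], path) -> pd.DataFrame:
    """Write species_summary.csv (one row per species) and return the table."""
    df = pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "order": s.order,
                "n_specimens": s.n_specimens,
                "avg_within": s.avg_within,
                "nn_distance": s.nn_distance,
                "training_status": s.training_status,
                "glmm_score": s.glmm_score,
                "category": s.category,
            }
            for s in stats
        ],
        columns=SUMMARY_COLUMNS,
    )
    df.to_csv(path, index=False)
    return df


def read_species_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SUMMARY_COLUMNS, path)
    return df


def write_distance_matrix_phylip(ids: list[str], d, path) -> None:
    """Export a square distance matrix in PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, sid in enumerate(ids):
            row = " ".join(f"{x:.6f}" for x in d[i])
            fh.write(f"{sid:<12s}{row}\n")


def write_distance_matrix_long(ids: list[str], d, sites, path) -> None:
    """Export pairwise distances in long form: id_a, id_b, distance, sites."""
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], d[i, j], int(sites[i, j])))
    pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "sites"]).to_csv(
        path, index=False
    )
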