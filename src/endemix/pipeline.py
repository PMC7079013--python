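"""End-to-end orchestration: filter -> delimit -> stats -> taxonomy ->
model fit/selection -> predict -> categorize -> report.

Every stage writes its CSV artifact into the output directory, and a JSON
run manifest records configuration, seed, software versions and the
specimen counts entering/leaving each filter, so a rerun with identical
inputs and configuration reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path


import numpy as np
import pandas as pd

from . import __version__, delimit, distances, filters, formats, glmm, taxonomy
from .records import SpecimenRecord

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    distance_model: str = "k2p"  # "k2p" or "p"
    linkage: str = "mean"
    min_bp: int = 300
    min_overlap: int = 100
    gap: delimit.GapConfig = field(default_factory=delimit.GapConfig)
    ci_level: float = 0.95
    formulas: tuple = glmm.FORMULAS
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value config file; '#' comments allowed."""
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        gap_keys = {f.name for f in delimit.GapConfig.__dataclass_fields__.values()}
        gap_kwargs, kwargs = {}, {}
        for k, v in kv.items():
            target = gap_kwargs if k in gap_keys else kwargs
            target[k] = v
        for k in ("min_bp", "min_overlap", "seed"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        if "ci_level" in kwargs:
            kwargs["ci_level"] = float(kwargs["ci_level"])
        if "formulas" in kwargs:
            kwargs["formulas"] = tuple(kwargs["formulas"].split(","))
        for k in ("P_min", "P_max", "relative_gap_width"):
            if k in gap_kwargs:
                gap_kwargs[k] = float(gap_kwargs[k])
        for k in ("n_steps", "min_slope_window"):
            if k in gap_kwargs:
                gap_kwargs[k] = int(gap_kwargs[k])
        if gap_kwargs:
            kwargs["gap"] = delimit.GapConfig(**gap_kwargs)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    species: pd.DataFrame  # the species summary table
    model_comparison: pd.DataFrame
    best_fit: glmm.GLMMFit
    thresholds: glmm.CategoryThresholds
    error_report: glmm.ErrorReport
    partitions: dict[str, delimit.SpeciesPartition]
    manifest: dict


def load_inputs(cfg: PipelineConfig):
    in_dir = Path(cfg.input_dir)
    for required in ("metadata.csv", "checklist.csv", "tophits.tsv"):
        if not (in_dir / required).exists():
            raise StageError("load", f"missing input file {required}")
    meta = formats.read_metadata(in_dir / "metadata.csv")
    checklist = formats.read_checklist(in_dir / "checklist.csv")
    tophits = formats.read_tophits(in_dir / "tophits.tsv")
    orders = sorted(meta["order"].unique())
    alignments = {}
    for order in orders:
        fasta = in_dir / f"{order}.fasta"
        if not fasta.exists():
            raise StageError("load", f"missing alignment {fasta.name}")
        alignments[order] = formats.read_alignment(fasta, order)
    records = []
    seq_of = {
        sid: seq
        for aln in alignments.values()
        for sid, seq in zip(aln.ids, aln.seqs)
    }
    for row in meta.itertuples(index=False):
        if row.specimen_id not in seq_of:
            raise StageError("load", f"no sequence for specimen {row.specimen_id}")
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                order=row.order,
                sequence=seq_of[row.specimen_id],
                morph_species=row.morph_name or None,
                morph_rank=row.morph_rank or "none",
                tophit=tophits.get(row.specimen_id),
            )
        )
    return records, alignments, checklist


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "endemix_version": __version__,
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "counts": {},
    }

    records, alignments, checklist = load_inputs(cfg)
    manifest["counts"]["input_specimens"] = len(records)

    # ---- QC filters -------------------------------------------------------
    kept, removed_short = filters.filter_min_length(records, cfg.min_bp)
    kept, removed_contam = filters.filter_contaminants(kept)
    manifest["counts"]["removed_short"] = len(removed_short)
    manifest["counts"]["removed_contaminant"] = len(removed_contam)
    keep_ids = {r.specimen_id for r in kept}
    removed_overlap: list[str] = []
    filtered_alignments = {}
    for order, aln in alignments.items():
        sub = aln.subset([i for i in aln.ids if i in keep_ids])
        if sub.n == 0:
            continue
        sub, dropped = filters.filter_min_overlap(sub, cfg.min_overlap)
        removed_overlap.extend(dropped)
        if sub.n:
            filtered_alignments[order] = sub
    manifest["counts"]["removed_overlap"] = len(removed_overlap)
    dropped_ids = set(removed_overlap)
    kept = [r for r in kept if r.specimen_id not in dropped_ids]
    manifest["counts"]["retained_specimens"] = len(kept)
    records_by_order: dict[str, list[SpecimenRecord]] = {}
    for r in kept:
        records_by_order.setdefault(r.order, []).append(r)

    # ---- per-order delimitation, stats, taxonomy --------------------------
    partition_rows, curve_rows = [], []
    partitions: dict[str, delimit.SpeciesPartition] = {}
    all_stats = []
    identity_rows = []
    statuses: dict[str, str] = {}
    names: dict[str, taxonomy.SpeciesIdentity] = {}
    for order, aln in sorted(filtered_alignments.items()):
        try:
            dm = distances.pairwise_distances(aln, cfg.distance_model)
            part, curve, chosen_P = delimit.delimit_order(dm, cfg.gap, order)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("delimit", f"{order}: {exc}") from exc
        partitions[order] = part
        for P, n_ini, n_rec in curve.grid:
            curve_rows.append(
                {
                    "order": order,
                    "P": P,
                    "n_initial": n_ini,
                    "n_recursive": n_rec,
                    "chosen": bool(np.isclose(P, chosen_P)),
                }
            )
        for sid, gid in sorted(part.assignment.items()):
            partition_rows.append(
                {
                    "specimen_id": sid,
                    "order": order,
                    "species_id": gid,
                    "prior_P": chosen_P,
                    "kind": part.kind,
                }
            )
        stats = distances.species_stats(dm, part.assignment, order, cfg.linkage)
        idents = taxonomy.propagate_morphology(part, records_by_order[order])
        idents = taxonomy.propagate_reference_match(
            idents, part, records_by_order[order]
        )
        st = taxonomy.assign_training_status(idents, checklist)
        statuses.update(st)
        names.update(idents)
        for s in stats:
            s.training_status = st.get(s.species_id, "unknown")
        all_stats.extend(stats)
        for gid, ident in sorted(idents.items()):
            identity_rows.append(
                {
                    "species_id": gid,
                    "order": order,
                    "assigned_name": ident.assigned_name,
                    "assigned_rank": ident.assigned_rank,
                    "source": ident.source,
                    "training_status": st.get(gid, "unknown"),
                }
            )
    manifest["counts"]["species"] = len(all_stats)
    pd.DataFrame(partition_rows).to_csv(out / "partitions.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
    pd.DataFrame(identity_rows).to_csv(out / "identities.csv", index=False)

    # ---- model ------------------------------------------------------------
    training = [
        s
        for s in all_stats
        if s.training_status in ("endemic", "introduced")
        and s.avg_within is not None
        and s.nn_distance is not None
    ]
    manifest["counts"]["training_species"] = len(training)
    if len(training) < 10 or len({s.order for s in training}) < 2:
        raise StageError(
            "fit", f"too few training species ({len(training)}) for the mixed model"
        )
    _log_preliminary_tests(training)
    try:
        fits = [glmm.fit_glmm(training, f) for f in cfg.formulas]
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc
    comparison = glmm.compare_models(fits)
    comparison.to_csv(out / "model_comparison.csv", index=False)
    best_id = comparison["formula_id"].iloc[0]
    best = next(f for f in fits if f.formula_id == best_id)

    # ---- predict & categorize ---------------------------------------------
    scored = glmm.predict_scores(best, all_stats)
    score_of = dict(zip(scored["species_id"], scored["glmm_score"]))
    training_ids = {s.species_id for s in training}
    thr = glmm.thresholds_from_training(
        [score_of[s.species_id] for s in training],
        [s.training_status for s in training],
        level=cfg.ci_level,
    )
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {
                "introduced": {"mean": thr.intro_mean, "ci": list(thr.intro_ci)},
                "endemic": {"mean": thr.endemic_mean, "ci": list(thr.endemic_ci)},
                "level": thr.level,
            },
            fh,
            indent=2,
        )
    for s in all_stats:
        s.glmm_score = score_of.get(s.species_id)
        if s.glmm_score is not None and np.isnan(s.glmm_score):
            s.glmm_score = None
        s.category = glmm.categorize(s.glmm_score, thr)
    species_df = formats.write_species_summary(all_stats, out / "species_summary.csv")

    # ---- error report on the training-status species ----------------------
    report = glmm.error_report(
        [s.category for s in all_stats],
        [s.training_status for s in all_stats],
        [s.order for s in all_stats],
    )
    _write_error_report(report, out / "error_report.csv")
    manifest["counts"]["categorized_species"] = int(
        (species_df["category"] != glmm.LABEL_NA).sum()
    )
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        species=species_df,
        model_comparison=comparison,
        best_fit=best,
        thresholds=thr,
        error_report=report,
        partitions=partitions,
        manifest=manifest,
    )


def _log_preliminary_tests(training) -> None:
    """Welch's t tests comparing the two statistics between statuses."""
    import warnings

    end = [s for s in training if s.training_status == "endemic"]
    intro = [s for s in training if s.training_status == "introduced"]
    if len(end) < 2 or len(intro) < 2:
        return
    for attr in ("nn_distance", "avg_within"):
        try:
            res = glmm.welch_t(
                [getattr(s, attr) for s in end], [getattr(s, attr) for s in intro]
            )
            log.info(
                "Welch's t (%s, endemic vs introduced): t=%.3f df=%.1f p=%.3g",
                attr,
                res.statistic,
                res.df,
                res.p_value,
            )
        except ValueError:
            pass


def _write_error_report(report: glmm.ErrorReport, path) -> None:
    table = report.counts.copy()
    err = report.error_table()
    table[("introduced", "Error%")] = err["introduced"]
    table[("endemic", "Error%")] = err["endemic"]
    table = table.sort_index(axis=1)
    flat = table.copy()
    flat.columns = [f"{a}_{b}" for a, b in table.columns]
    flat.index.name = "order"
    flat.to_csv(path)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["gap"] = asdict(cfg.gap)
    d["formulas"] = list(cfg.formulas)
    return d
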