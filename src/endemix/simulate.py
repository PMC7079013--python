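"""Seeded generator of synthetic barcode communities.

Emulates the statistical structure of an oceanic-island arthropod barcode
survey: per order, an *endemic radiation* whose species sit close together
(small nearest-neighbor distances, default mean 0.05 substitutions/site)
and *introduced* lineages isolated on long branches (default 0.18), with
modest within-species diversity (defaults 0.0076 endemic / 0.0095
introduced), a partial biogeographic checklist, reference-library top hits,
and the two kinds of junk the QC stage must remove (short sequences and
order-level contaminants).

Sequences evolve under Jukes-Cantor substitution.  Endemic species
consensuses sit on a pure-birth (Yule) tree whose branch lengths are
rescaled so the realized mean nearest-neighbor mean-linkage distance hits
the target; node heights are capped at a quarter of the introduced target
so that radiation depth never rivals the endemic/introduced gap.
Introduced consensuses evolve on independent stems from the order's
ancestral sequence, long enough that their nearest neighbor (always across
the endemic/introduced divide or another introduced lineage) lands at the
introduced target.  Specimens scatter around their species consensus at
half the within-species target each, so within-species pairs average the
target.  An order-level lognormal factor rescales all of an order's
distances, giving the order-to-order heterogeneity the model's random
intercept absorbs.

Everything is reproducible from ``rng_seed``; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import Checklist, OrderAlignment, SpecimenRecord, TopHit
from . import formats

BASES = np.frombuffer(b"ACGT", dtype="S1")

ORDER_POOL = [
    "Araneae",
    "Blattodea",
    "Coleoptera",
    "Diptera",
    "Hemiptera",
    "Hymenoptera",
    "Lepidoptera",
    "Neuroptera",
    "Odonata",
    "Psocoptera",
    "Thysanoptera",
]


@dataclass
class SimConfig:
    n_orders: int = 8
    n_endemic_species: int = 10
    n_introduced_species: int = 10
    n_unknown_species: int = 10
    specimens_per_species_mean: float = 4.0  # zero-truncated Poisson
    singleton_fraction: float = 0.1
    seq_length: int = 650
    endemic_nn_target: float = 0.05
    introduced_nn_target: float = 0.18
    within_target_endemic: float = 0.0076
    within_target_introduced: float = 0.0095
    checklist_coverage: float = 0.7
    contaminant_fraction: float = 0.02
    short_seq_fraction: float = 0.02
    morph_id_fraction: float = 0.6  # specimens of named species with morph IDs
    order_effect_sd: float = 0.25  # lognormal sd of per-order distance scale
    introduced_diversity_widening: float = 1.0  # >1 mimics multiple introductions
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "singleton_fraction",
            "checklist_coverage",
            "contaminant_fraction",
            "short_seq_fraction",
            "morph_id_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        worst_within = max(self.within_target_endemic, self.within_target_introduced)
        if self.endemic_nn_target < 3 * worst_within:
            raise ValueError(
                "infeasible targets: endemic nearest-neighbor distance must be "
                "at least 3x the within-species targets for a delimitable gap"
            )
        if self.introduced_nn_target <= self.endemic_nn_target:
            raise ValueError("introduced_nn_target must exceed endemic_nn_target")


@dataclass
class SimulatedCommunity:
    config: SimConfig
    records: list[SpecimenRecord]
    alignments: dict[str, OrderAlignment]
    truth: pd.DataFrame  # specimen_id, order, true_species, species_name, true_status
    checklist: Checklist
    tophits: dict[str, TopHit]

    def write(self, out_dir) -> None:
        """Write the community in the pipeline's input formats, plus
        truth.csv for evaluation."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for order, aln in self.alignments.items():
            formats.write_alignment(aln, out / f"{order}.fasta")
        meta = pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in self.records],
                "order": [r.order for r in self.records],
                "morph_rank": [r.morph_rank for r in self.records],
                "morph_name": [r.morph_species or "" for r in self.records],
            }
        )
        meta.to_csv(out / "metadata.csv", index=False)
        rows = []
        for r in self.records:
            h = self.tophits.get(r.specimen_id)
            rows.append(
                {
                    "query_id": r.specimen_id,
                    "pct_identity": "" if h is None else f"{h.identity:.2f}",
                    "hit_species": (h.species or "") if h else "",
                    "hit_genus": (h.genus or "") if h else "",
                    "hit_family": (h.family or "") if h else "",
                    "hit_order": (h.order or "") if h else "",
                }
            )
        pd.DataFrame(rows).to_csv(out / "tophits.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.checklist.entries.items()),
            columns=["species_name", "status"],
        ).to_csv(out / "checklist.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


# --------------------------------------------------------------------------
# sequence evolution


def _random_seq(rng, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _evolve_jc(rng, seq: np.ndarray, d: float) -> np.ndarray:
    """Evolve a sequence along a branch of expected ``d`` substitutions per
    site under Jukes-Cantor: each site differs with probability
    3/4 (1 - exp(-4d/3)), landing uniformly on the other three bases."""
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = rng.random(len(seq)) < p_diff
    n_hit = int(hit.sum())
    if n_hit:
        lookup = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(BASES):
            lookup[b[0]] = i
        idx = lookup[out[hit].view(np.uint8)]
        shift = rng.integers(1, 4, size=n_hit)
        out[hit] = BASES[(idx + shift) % 4]
    return out


# --------------------------------------------------------------------------
# pure-birth tree of endemic consensus sequences


def _yule_divergence_heights(rng, n_tips: int) -> np.ndarray:
    """Simulate a Yule tree and return the (n, n) matrix of node heights
    (time back from the tips) of each pair's most recent common ancestor.
    The tree is ultrametric, so tip-to-tip distance = 2 * height."""
    if n_tips == 1:
        return np.zeros((1, 1))
    # forward simulation: lineages split at exponential times
    split_time = {}  # node id -> time its children were born
    parent = {}
    t = 0.0
    lineages = [0]
    next_id = 1
    while len(lineages) < n_tips:
        t += rng.exponential(1.0 / len(lineages))
        splitter = lineages[rng.integers(0, len(lineages))]
        a, b = next_id, next_id + 1
        next_id += 2
        parent[a] = splitter
        parent[b] = splitter
        split_time[splitter] = t
        lineages.remove(splitter)
        lineages.extend([a, b])
    # one final waiting time so terminal branches have positive length
    T = t + rng.exponential(1.0 / len(lineages))

    def ancestors(node):
        chain = {}
        while node in parent:
            node = parent[node]
            chain[node] = split_time[node]
        return chain

    heights = np.zeros((n_tips, n_tips))
    chains = [ancestors(tip) for tip in lineages]
    for i in range(n_tips):
        for j in range(i + 1, n_tips):
            common = set(chains[i]) & set(chains[j])
            mrca_split = max(chains[i][c] for c in common)
            heights[i, j] = heights[j, i] = T - mrca_split
    return heights


def _scale_endemic_tree(
    heights: np.ndarray,
    nn_target_consensus: float,
    height_cap: float,
    height_floor: float = 0.0,
) -> np.ndarray:
    """Scale (floor, cap) Yule node heights so the mean over species of the
    minimum tip-to-tip distance equals ``nn_target_consensus``.

    Solved by bisection on the scale factor.  Heights above ``height_cap``
    are compressed to the cap so the radiation never approaches the
    endemic/introduced divide; heights below ``height_floor`` are lifted to
    the floor so no species pair sits closer than the within-species
    diversity it must be distinguishable from (raw Yule trees produce
    arbitrarily shallow cherries).  Monotone transforms of an ultrametric
    height matrix stay ultrametric.
    """
    n = heights.shape[0]
    if n == 1:
        return heights

    def transform(scale: float) -> np.ndarray:
        return np.clip(heights * scale, height_floor, height_cap)

    def realized_mean_nn(scale: float) -> float:
        d = 2.0 * transform(scale)
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())

    lo, hi = 1e-6, 1.0
    while realized_mean_nn(hi) < nn_target_consensus and hi < 1e6:
        hi *= 2.0
    if realized_mean_nn(hi) < nn_target_consensus:
        # cap binds for every pair; best achievable is the cap itself
        return transform(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized_mean_nn(mid) < nn_target_consensus:
            lo = mid
        else:
            hi = mid
    return transform(hi)


def _consensus_from_heights(rng, ancestral: np.ndarray, heights: np.ndarray):
    """Generate tip sequences consistent with an ultrametric height matrix
    by hierarchical splitting (UPGMA-like traversal of the height matrix)."""
    n = heights.shape[0]
    seqs: list[Optional[np.ndarray]] = [None] * n
    depth = float(heights.max()) if n > 1 else 0.0
    root = _evolve_jc(rng, ancestral, 0.0)

    def descend(tips: list[int], seq: np.ndarray, remaining: float) -> None:
        if len(tips) == 1:
            seqs[tips[0]] = _evolve_jc(rng, seq, remaining)
            return
        sub = heights[np.ix_(tips, tips)]
        np.fill_diagonal(sub, 0.0)
        h = float(sub.max())  # height of this clade's root
        # branch from current position down to this clade's split
        seq = _evolve_jc(rng, seq, max(remaining - h, 0.0))
        # split tips into the two clades meeting at height h
        first = tips[0]
        left = [t for t in tips if heights[first, t] < h - 1e-12 or t == first]
        right = [t for t in tips if t not in left]
        if not right:  # numerical tie: split off the first tip
            left, right = [tips[0]], tips[1:]
        descend(left, seq, h)
        descend(right, seq, h)

    descend(list(range(n)), root, depth)
    return [s for s in seqs]


# --------------------------------------------------------------------------
# community assembly


def simulate_community(cfg: SimConfig) -> SimulatedCommunity:
    """Generate one synthetic community (records, truth, checklist, hits)."""
    rng = np.random.default_rng(cfg.rng_seed)
    orders = [ORDER_POOL[i % len(ORDER_POOL)] for i in range(cfg.n_orders)]
    if cfg.n_orders > len(ORDER_POOL):
        orders = [f"{o}{i}" for i, o in enumerate(orders)]

    records: list[SpecimenRecord] = []
    truth_rows = []
    checklist_entries: dict[str, str] = {}
    tophits: dict[str, TopHit] = {}
    alignments: dict[str, OrderAlignment] = {}

    for order in orders:
        order_scale = float(np.exp(rng.normal(0.0, cfg.order_effect_sd)))
        w_e = cfg.within_target_endemic * order_scale
        w_i = cfg.within_target_introduced * order_scale * cfg.introduced_diversity_widening
        nn_e = cfg.endemic_nn_target * order_scale
        nn_i = cfg.introduced_nn_target * order_scale

        # species inventory: unknown-status species alternate between the
        # two structural types so both appear outside the checklist
        species = []  # (name, structural type, checklist status known?)
        for k in range(cfg.n_endemic_species):
            species.append((f"{order} endspecies{k}", "endemic", True))
        for k in range(cfg.n_introduced_species):
            species.append((f"{order} intspecies{k}", "introduced", True))
        for k in range(cfg.n_unknown_species):
            kind = "endemic" if k % 2 == 0 else "introduced"
            species.append((f"{order} unkspecies{k}", kind, False))

        endemic_idx = [i for i, s in enumerate(species) if s[1] == "endemic"]
        introduced_idx = [i for i, s in enumerate(species) if s[1] == "introduced"]

        # specimen counts fixed up front so the calibration passes below see
        # the same community layout
        n_spec_of: list[int] = []
        for _ in species:
            if rng.random() < cfg.singleton_fraction:
                n_spec_of.append(1)
            else:
                n = 0
                while n < 1:
                    n = int(rng.poisson(cfg.specimens_per_species_mean))
                n_spec_of.append(n)

        order_seed = int(rng.integers(2**31))

        def generate(cons_nn_target: float, stem_extra: float):
            """One realization of the order's sequences from a fixed seed.

            Endemic consensuses evolve on the rescaled Yule tree; introduced
            consensuses on independent stems from the ancestral sequence;
            specimens scatter around their consensus.
            """
            g = np.random.default_rng(order_seed)
            ancestral = _random_seq(g, cfg.seq_length)
            heights = _yule_divergence_heights(g, max(len(endemic_idx), 1))
            height_cap = nn_i / 4.0
            # no two species closer than 5x the within-species diversity:
            # keeps every simulated species boundary outside the within-
            # distance noise cloud at barcode-length sequences
            height_floor = 2.5 * w_e
            scaled = _scale_endemic_tree(
                heights, max(cons_nn_target, 1e-4), height_cap, height_floor
            )
            endemic_seqs = _consensus_from_heights(g, ancestral, scaled)
            depth = float(scaled.max()) if len(endemic_idx) > 1 else 0.0
            consensus: dict[int, np.ndarray] = {}
            for pos, sp_i in enumerate(endemic_idx):
                consensus[sp_i] = endemic_seqs[pos]
            stem = max(nn_i - depth - 0.5 * (w_e + w_i) + stem_extra, 0.02)
            for sp_i in introduced_idx:
                consensus[sp_i] = _evolve_jc(g, ancestral, stem)
            out: dict[int, list[np.ndarray]] = {}
            for sp_i, (_, kind, _) in enumerate(species):
                w = w_e if kind == "endemic" else w_i
                out[sp_i] = [
                    _evolve_jc(g, consensus[sp_i], w / 2.0)
                    for _ in range(n_spec_of[sp_i])
                ]
            return out

        def realized_nn_means(seqs_by_sp):
            """Measure the realized per-type mean nearest-neighbor distance
            with the package's own distance machinery."""
            from .distances import pairwise_distances, species_stats

            ids_, rows_, assign = [], [], {}
            for sp_i, sp_seqs in seqs_by_sp.items():
                for j, s in enumerate(sp_seqs):
                    sid = f"c{sp_i}_{j}"
                    ids_.append(sid)
                    rows_.append(s.tobytes().decode("ascii"))
                    assign[sid] = str(sp_i)
            aln = OrderAlignment(order=order, ids=ids_, seqs=rows_)
            dm = pairwise_distances(aln, "k2p")
            stats = species_stats(dm, assign, order)
            by_type = {"endemic": [], "introduced": []}
            for st in stats:
                if st.nn_distance is not None:
                    by_type[species[int(st.species_id)][1]].append(st.nn_distance)
            return (
                float(np.mean(by_type["endemic"])) if by_type["endemic"] else None,
                float(np.mean(by_type["introduced"])) if by_type["introduced"] else None,
            )

        # the nearest-neighbor statistic is a minimum over noisy realized
        # distances and so sits below the naive expectation; two calibration
        # passes with common random numbers correct branch lengths until the
        # realized means hit the targets
        cons_target = max(nn_e - w_e, 1e-4)
        stem_extra = 0.0
        seqs_by_sp = generate(cons_target, stem_extra)
        for _ in range(2):
            r_e, r_i = realized_nn_means(seqs_by_sp)
            if r_e is not None and r_e > 0:
                cons_target = max(cons_target + (nn_e - r_e), 1e-4)
            if r_i is not None:
                stem_extra += nn_i - r_i
            seqs_by_sp = generate(cons_target, stem_extra)

        # specimens
        ids, seq_rows = [], []
        for sp_i, (name, kind, listed) in enumerate(species):
            for j in range(n_spec_of[sp_i]):
                sid = f"{order[:4].upper()}{sp_i:03d}_{j:02d}"
                ids.append(sid)
                seq_rows.append(seqs_by_sp[sp_i][j])
                truth_rows.append(
                    {
                        "specimen_id": sid,
                        "order": order,
                        "true_species": f"{order}:{sp_i}",
                        "species_name": name,
                        "true_status": kind if listed else "unknown",
                        "true_type": kind,
                    }
                )

        # per-specimen annotations
        order_truth = truth_rows[-len(ids):]
        for pos, (row, sid) in enumerate(zip(order_truth, ids)):
            sp_i = int(row["true_species"].split(":")[1])
            name, kind, listed = species[sp_i]
            morph_species, morph_rank = None, "order"
            if listed and rng.random() < cfg.morph_id_fraction:
                morph_species, morph_rank = name, "species"
            row["morph_rank"] = morph_rank

            # top hits: introduced lineages are cosmopolitan and well
            # represented in reference libraries; endemics are not
            contaminant = rng.random() < cfg.contaminant_fraction
            hit_order = order
            if contaminant:
                hit_order = next(o for o in ORDER_POOL if o != order)
            if kind == "introduced":
                identity = float(rng.uniform(97.0, 100.0))
                hit = TopHit(
                    identity=identity,
                    species=name if listed else None,
                    genus=name.split()[1][:6].capitalize(),
                    family=f"{order}idae",
                    order=hit_order,
                )
            else:
                identity = float(rng.uniform(75.0, 92.0))
                hit = TopHit(
                    identity=identity,
                    species=None,
                    genus=None if identity < 90 else f"Gen{sp_i}",
                    family=f"{order}idae",
                    order=hit_order,
                )
            tophits[sid] = hit

            seq = seq_rows[pos]
            if rng.random() < cfg.short_seq_fraction:
                keep = int(rng.integers(100, 300))
                short = np.full(cfg.seq_length, b"-", dtype="S1")
                short[:keep] = seq[:keep]
                seq_rows[pos] = short

            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    order=order,
                    sequence=seq_rows[pos].tobytes().decode("ascii"),
                    morph_species=morph_species,
                    morph_rank=morph_rank,
                    tophit=hit,
                )
            )

        alignments[order] = OrderAlignment(
            order=order,
            ids=ids,
            seqs=[s.tobytes().decode("ascii") for s in seq_rows],
        )

        # checklist: covers a fraction of the named species
        for name, kind, listed in species:
            if listed and rng.random() < cfg.checklist_coverage:
                checklist_entries[Checklist.normalize(name)] = kind

    truth = pd.DataFrame(truth_rows)
    return SimulatedCommunity(
        config=cfg,
        records=records,
        alignments=alignments,
        truth=truth,
        checklist=Checklist(entries=checklist_entries),
        tophits=tophits,
    )


# --------------------------------------------------------------------------
# evaluation against simulated truth


def truth_eval(
    categories: dict[str, str],
    members: dict[str, list[str]],
    truth: pd.DataFrame,
):
    """Score predicted categorizations against the simulated truth.

    ``categories`` maps delimited species ids to their labels and
    ``members`` to their specimen ids; a delimited species inherits the
    majority structural type (endemic/introduced) of its members.  Returns
    the per-category contingency report (see
    :class:`endemix.glmm.ErrorReport`) built over *all* species with a true
    type — checklisted or not — plus the complement-of-mean-error accuracy.
    """
    from .glmm import error_report

    type_of = dict(zip(truth["specimen_id"], truth["true_type"]))
    order_of = dict(zip(truth["specimen_id"], truth["order"]))
    labels, statuses, orders = [], [], []
    for sp, label in categories.items():
        specs = [m for m in members.get(sp, []) if m in type_of]
        if not specs:
            continue
        kinds = pd.Series([type_of[m] for m in specs])
        labels.append(label)
        statuses.append(kinds.mode().iloc[0])
        orders.append(order_of[specs[0]])
    report = error_report(labels, statuses, orders)
    return report, report.accuracy()
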