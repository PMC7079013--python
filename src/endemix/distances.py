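"""Pairwise nucleotide distances and per-species diversity statistics.

Distances use pairwise deletion: for each sequence pair, alignment columns
where either member carries anything other than an unambiguous A/C/G/T are
excluded.  Two models are available:

* ``p`` — uncorrected proportion of mismatching comparable sites;
* ``k2p`` — Kimura two-parameter correction,
  ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the transition
  and transversion proportions.  When the correction is undefined for a
  pair (logarithm of a non-positive number, i.e. near-saturated
  divergence) the pair falls back to its p-distance and a warning is
  logged.

Two statistics per delimited species drive the downstream model: the mean
pairwise distance among its own specimens (``avg_within``) and the
mean-linkage distance to its nearest-neighbor species (``nn_distance``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import OrderAlignment, SpeciesStats

log = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_PURINE = np.array([True, False, True, False])  # A, G


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # (n, n) float, symmetric, zero diagonal
    model: str
    comparable_sites: np.ndarray = field(repr=False, default=None)  # (n, n) int

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            d=self.d[np.ix_(idx, idx)],
            model=self.model,
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)],
        )


def _encode(aln: OrderAlignment) -> np.ndarray:
    return _CODE[aln.matrix.view(np.uint8)]


def pairwise_distances(aln: OrderAlignment, model: str = "k2p") -> DistanceMatrix:
    """Compute the pairwise distance matrix for one order's alignment.

    Assumes the alignment already passed the overlap filter, so every pair
    retains at least one comparable site.
    """
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    codes = _encode(aln)
    n = codes.shape[0]
    valid = codes >= 0
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    k2p_fallbacks = 0
    for i in range(n):
        vi = valid[i]
        ci = codes[i]
        both = vi & valid[i + 1 :]
        ns = both.sum(axis=1)
        mism = ((ci != codes[i + 1 :]) & both)
        nm = mism.sum(axis=1)
        sites[i, i + 1 :] = ns
        with np.errstate(divide="ignore", invalid="ignore"):
            p_dist = np.where(ns > 0, nm / np.maximum(ns, 1), 0.0)
        if model == "p":
            d[i, i + 1 :] = p_dist
            continue
        # transitions: mismatching sites where both bases are purines or both
        # pyrimidines (A<->G, C<->T)
        same_class = _PURINE[np.clip(ci, 0, 3)] == _PURINE[np.clip(codes[i + 1 :], 0, 3)]
        ts = (mism & same_class).sum(axis=1)
        tv = nm - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(ns > 0, ts / np.maximum(ns, 1), 0.0)
            Q = np.where(ns > 0, tv / np.maximum(ns, 1), 0.0)
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            k2p = -0.5 * np.log(a1) - 0.25 * np.log(a2)
        ok = (a1 > 0) & (a2 > 0)
        k2p_fallbacks += int((~ok & (ns > 0)).sum())
        d[i, i + 1 :] = np.where(ok, k2p, p_dist)
    if k2p_fallbacks:
        log.warning(
            "K2P undefined for %d pair(s) in %s; used p-distance for those",
            k2p_fallbacks,
            aln.order,
        )
    d = d + d.T
    sites = sites + sites.T
    np.fill_diagonal(sites, valid.sum(axis=1))
    return DistanceMatrix(ids=list(aln.ids), d=d, model=model, comparable_sites=sites)


def species_stats(
    dm: DistanceMatrix,
    assignment: dict[str, str],
    order: str,
    linkage: str = "mean",
) -> list[SpeciesStats]:
    """Per-species average within-species distance and nearest-neighbor
    between-species distance.

    ``assignment`` maps every specimen id in ``dm`` to a species id.
    Between-species distance uses mean linkage by default (the mean over all
    cross pairs); ``linkage="single"`` (minimum cross pair) is available for
    sensitivity analyses.  Results are invariant to specimen ordering.
    """
    if not assignment:
        raise ValueError("empty species assignment")
    missing = [sid for sid in dm.ids if sid not in assignment]
    if missing:
        raise ValueError(f"specimens missing from assignment: {missing[:5]}")
    if linkage not in ("mean", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")

    species = sorted({assignment[sid] for sid in dm.ids})
    masks = {
        sp: np.array([assignment[sid] == sp for sid in dm.ids]) for sp in species
    }
    out: list[SpeciesStats] = []
    for sp in species:
        m = masks[sp]
        k = int(m.sum())
        if k >= 2:
            block = dm.d[np.ix_(m, m)]
            iu = np.triu_indices(k, 1)
            avg_within = float(block[iu].mean())
        else:
            avg_within = None
        nn = None
        if len(species) > 1:
            best = np.inf
            for other in species:
                if other == sp:
                    continue
                cross = dm.d[np.ix_(m, masks[other])]
                val = float(cross.mean() if linkage == "mean" else cross.min())
                if val < best:
                    best = val
            nn = best
        out.append(
            SpeciesStats(
                species_id=sp,
                order=order,
                n_specimens=k,
                avg_within=avg_within,
                nn_distance=nn,
            )
        )
    return out
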