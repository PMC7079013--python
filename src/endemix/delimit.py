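"""Barcode-gap species delimitation.

Specimens are clustered into species-groups (OTUs) per order by recursive
barcode-gap detection, in the spirit of Automatic Barcode Gap Discovery
(ABGD): for a grid of prior maximum intraspecific divergences P, find the
first significant widening ("gap") in the sorted pairwise distances above
P, split the specimens by single-linkage at the gap midpoint, and re-apply
the procedure inside each group until nothing splits (the *recursive*
partition; the one-pass result is the *initial* partition).

The gap-significance rule is a deliberate simplification of ABGD's slope
test: scanning consecutive gaps ``g_i = d_(i+1) - d_(i)`` restricted to
``d_(i) >= P``, with a local slope ``theta_i`` estimated as the median gap
over a trailing window, a gap is significant when ``g_i > X * theta_i``
and ``g_i > P * (X - 1)`` for a relative width X (default 1.5).  Exact
numerical equivalence with the original C implementation is not claimed.

The working prior P is chosen where the initial and recursive group counts
meet (the point where the two curves intersect); the recursive partition at
that P is the final species assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

log = logging.getLogger(__name__)

MAX_RECURSION_DEPTH = 20


@dataclass
class GapConfig:
    """Barcode-gap scan parameters (ABGD-style defaults)."""

    P_min: float = 0.001
    P_max: float = 0.1
    n_steps: int = 10
    relative_gap_width: float = 1.5  # X
    min_slope_window: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.P_min < self.P_max):
            raise ValueError("need 0 < P_min < P_max")
        if self.relative_gap_width <= 1:
            raise ValueError("relative_gap_width must exceed 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")

    def grid(self) -> np.ndarray:
        """Log-spaced prior grid from P_min to P_max."""
        return np.geomspace(self.P_min, self.P_max, self.n_steps)


@dataclass
class SpeciesPartition:
    order: str
    prior_P: float
    assignment: dict[str, str]  # specimen id -> species-group id
    kind: str = "initial"  # initial | recursive

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class PartitionCurve:
    order: str
    grid: list[tuple[float, int, int]] = field(default_factory=list)
    # (P, n_groups_initial, n_groups_recursive)


def detect_gap(sorted_distances, P: float, cfg: GapConfig | None = None):
    """Locate the first significant gap among sorted distances above prior P.

    A gap ``g_i = d_(i+1) - d_(i)`` (with ``d_(i) >= P``) is significant
    when it exceeds ``X`` times the local slope ``theta_i`` — the largest
    gap over a trailing window of ``min_slope_window`` gaps — and exceeds
    ``P * (X - 1)``.  The maximum (rather than an average) makes the rule
    robust to the heavy ties of distances quantized by a finite alignment
    length: a barcode gap has to dominate every recent gap, not just the
    typical one.  Returns the midpoint of the first such gap, or None.
    """
    cfg = cfg or GapConfig()
    d = np.asarray(sorted_distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if d.size == 1:
        return None
    gaps = np.diff(d)
    X = cfg.relative_gap_width
    w = cfg.min_slope_window
    for i in range(len(gaps)):
        if d[i] < P:
            continue
        lo = max(0, i - w)
        window = gaps[lo:i]
        theta = float(window.max()) if window.size else 0.0
        if theta == 0.0:
            # ties (distances quantized by alignment length) can fill the
            # whole window; reach back to the most recent non-zero gap
            prev = np.flatnonzero(gaps[:i] > 0)
            if prev.size:
                theta = float(gaps[prev[-1]])
            else:
                # scan starts here: judge against what follows instead
                fwd = gaps[i + 1 : i + 1 + w]
                if not fwd.size:
                    break  # single gap, nothing to compare against
                theta = float(fwd.max())
        g = gaps[i]
        if g > X * theta and g > P * (X - 1):
            return float((d[i] + d[i + 1]) / 2.0)
    return None


def partition_at_threshold(dm: DistanceMatrix, threshold: float) -> SpeciesPartition:
    """Single-linkage grouping: connected components of the graph linking
    pairs with distance strictly below ``threshold``.

    Group ids are the lexicographically smallest member id, so partitions
    are stable across input orderings.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    adj = csr_matrix(dm.d < threshold)
    _, labels = connected_components(adj, directed=False)
    assignment: dict[str, str] = {}
    group_name: dict[int, str] = {}
    for lab in np.unique(labels):
        members = [dm.ids[i] for i in np.where(labels == lab)[0]]
        group_name[lab] = min(members)
    for i, sid in enumerate(dm.ids):
        assignment[sid] = group_name[labels[i]]
    return SpeciesPartition(order="", prior_P=np.nan, assignment=assignment)


def _upper_distances(dm: DistanceMatrix) -> np.ndarray:
    iu = np.triu_indices(dm.n, 1)
    return np.sort(dm.d[iu])


def initial_partition(
    dm: DistanceMatrix, P: float, cfg: GapConfig | None = None, order: str = ""
) -> SpeciesPartition:
    """One-pass barcode-gap partition of a full distance matrix."""
    cfg = cfg or GapConfig()
    if dm.n == 1:
        part = SpeciesPartition(order, P, {dm.ids[0]: dm.ids[0]}, kind="initial")
        return part
    thr = detect_gap(_upper_distances(dm), P, cfg)
    if thr is None:
        assignment = {sid: min(dm.ids) for sid in dm.ids}
    else:
        assignment = partition_at_threshold(dm, thr).assignment
    return SpeciesPartition(order=order, prior_P=P, assignment=assignment, kind="initial")


def recursive_partition(
    dm: DistanceMatrix, P: float, cfg: GapConfig | None = None, order: str = ""
) -> SpeciesPartition:
    """Initial partition, then re-split inside each group until stable."""
    cfg = cfg or GapConfig()
    part = initial_partition(dm, P, cfg, order)
    assignment = dict(part.assignment)
    id_index = {sid: i for i, sid in enumerate(dm.ids)}

    depth = 0
    changed = True
    while changed:
        depth += 1
        if depth > MAX_RECURSION_DEPTH:
            log.warning("recursive partition depth cap reached for %s", order)
            break
        changed = False
        for group in sorted(set(assignment.values())):
            members = [sid for sid, g in assignment.items() if g == group]
            if len(members) < 3:
                continue
            idx = np.array([id_index[m] for m in members])
            sub = dm.submatrix(idx)
            thr = detect_gap(_upper_distances(sub), P, cfg)
            if thr is None:
                continue
            sub_part = partition_at_threshold(sub, thr)
            if len(set(sub_part.assignment.values())) > 1:
                assignment.update(sub_part.assignment)
                changed = True
    return SpeciesPartition(order=order, prior_P=P, assignment=assignment, kind="recursive")


def partition_curve(
    dm: DistanceMatrix, cfg: GapConfig | None = None, order: str = ""
) -> PartitionCurve:
    """Initial and recursive group counts across the prior grid."""
    cfg = cfg or GapConfig()
    curve = PartitionCurve(order=order)
    for P in cfg.grid():
        ini = initial_partition(dm, P, cfg, order)
        rec = recursive_partition(dm, P, cfg, order)
        curve.grid.append((float(P), ini.n_groups, rec.n_groups))
    return curve


def choose_optimal_P(curve: PartitionCurve) -> float:
    """Prior at which the initial and recursive species-count curves meet.

    Returns the smallest grid P with equal counts; when the two curves
    diverge somewhere on the grid (recursive above initial, the usual shape
    at small priors), only equalities at or after the divergence count —
    at very small priors both passes can shatter the data into
    near-singleton groups and agree trivially, which is not the
    convergence point the rule is after.  If the counts are never equal,
    the P minimizing their absolute difference (ties to smaller P).
    """
    if not curve.grid:
        raise ValueError("empty partition curve")
    Ps = [P for P, _, _ in curve.grid]
    ini = [n for _, n, _ in curve.grid]
    rec = [n for _, _, n in curve.grid]
    m = len(rec)

    # locate the knee: the largest single-step drop of the recursive curve
    # marks the transition out of the oversplit regime (priors below the
    # within-species diversity shatter the data into near-singletons on
    # both passes).  Drops into the single-group level are the opposite
    # degeneracy (prior beyond the barcode gap) and are skipped.
    drops = [rec[i] - rec[i + 1] for i in range(m - 1)]
    knee = 0
    for i in sorted(range(m - 1), key=lambda i: (-drops[i], i)):
        if drops[i] <= 0:
            break
        if rec[i + 1] > 1:
            knee = i + 1
            break

    # the knee plateau: consecutive priors whose recursive counts stay
    # within 25% of the knee count
    end = knee
    while end + 1 < m and rec[end + 1] >= 0.75 * rec[knee]:
        end += 1
    window = range(knee, end + 1)
    for j in window:
        if ini[j] == rec[j]:
            return Ps[j]
    best = min(window, key=lambda j: (abs(rec[j] - ini[j]), Ps[j]))
    return Ps[best]


def delimit_order(
    dm: DistanceMatrix, cfg: GapConfig | None = None, order: str = ""
) -> tuple[SpeciesPartition, PartitionCurve, float]:
    """Full per-order delimitation: curve, optimal P, and the recursive
    partition at that P (the final species assignment)."""
    cfg = cfg or GapConfig()
    curve = partition_curve(dm, cfg, order)
    P = choose_optimal_P(curve)
    part = recursive_partition(dm, P, cfg, order)
    return part, curve, P
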