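"""Multi-objective evolutionary machinery.

Implements the immune-inspired global search layer: Pareto dominance and
nondominated filtering, NSGA-II crowding distance, dominant/active
population selection, proportional cloning, one-way crossover for the
group-based encoding, and neighbor-restricted mutation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .encoding import Individual
from .graph_core import Graph
from .objectives import ObjectivePoint

__all__ = [
    "dominates",
    "nondominated_filter",
    "crowding_distance",
    "truncate_dominant",
    "select_active",
    "proportional_clone",
    "one_way_crossover",
    "neighbor_mutation",
]


def dominates(a: ObjectivePoint, b: ObjectivePoint) -> bool:
    """True iff a is >= b in both objectives and > in at least one."""
    return (
        a.intra >= b.intra
        and a.inter >= b.inter
        and (a.intra > b.intra or a.inter > b.inter)
    )


def _objective_matrix(pop: Sequence[Individual]) -> np.ndarray:
    pts = []
    for ind in pop:
        if ind.objectives is None:
            raise ValueError("population member has no evaluated objectives")
        pts.append(ind.objectives.as_tuple())
    return np.asarray(pts, dtype=float)


def nondominated_filter(pop: Sequence[Individual]) -> list[Individual]:
    """Members not dominated by any other member (pairwise, order-stable)."""
    if not pop:
        return []
    f = _objective_matrix(pop)
    keep = []
    for i in range(len(pop)):
        ge = (f[:, 0] >= f[i, 0]) & (f[:, 1] >= f[i, 1])
        gt = (f[:, 0] > f[i, 0]) | (f[:, 1] > f[i, 1])
        if not np.any(ge & gt):
            keep.append(pop[i])
    return keep


def crowding_distance(points: Sequence[ObjectivePoint] | np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance over the two objectives.

    Boundary points get +inf; interior points sum, per objective, the gap
    between their neighbors normalized by that objective's range within the
    set being ranked.  A zero range contributes nothing.
    """
    if isinstance(points, np.ndarray):
        f = np.asarray(points, dtype=float)
    else:
        f = np.asarray([p.as_tuple() for p in points], dtype=float)
    nump = f.shape[0]
    if nump == 0:
        return np.empty(0)
    dist = np.zeros(nump)
    for j in range(f.shape[1]):
        order = np.argsort(f[:, j], kind="stable")
        span = f[order[-1], j] - f[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and nump > 2:
            gaps = (f[order[2:], j] - f[order[:-2], j]) / span
            dist[order[1:-1]] += gaps
    return dist


def _by_descending_distance(pop: Sequence[Individual]) -> list[Individual]:
    d = crowding_distance(_objective_matrix(pop))
    order = np.argsort(-d, kind="stable")  # stable: ties keep original order
    return [pop[i] for i in order]


def truncate_dominant(pop: Sequence[Individual], sd: int) -> list[Individual]:
    """Keep at most ``sd`` members, preferring larger crowding distance."""
    if len(pop) <= sd:
        return list(pop)
    return _by_descending_distance(pop)[:sd]


def select_active(dominant: Sequence[Individual], sa: int) -> list[Individual]:
    """First ``sa`` dominant members by descending crowding distance.

    The caller keeps the untruncated dominant population separately as the
    elitism archive.
    """
    if len(dominant) <= sa:
        return list(dominant)
    return _by_descending_distance(dominant)[:sa]


def proportional_clone(active: Sequence[Individual], sc: int) -> list[Individual]:
    """Copy each active member q_i >= 1 times with sum(q_i) = sc.

    Quotas are proportional to the member's crowding-distance share, with
    infinite (boundary) distances capped at twice the largest finite
    distance (1 if none is finite); rounding by largest remainder.  Less
    crowded members therefore receive more clones.
    """
    na = len(active)
    if na == 0:
        raise ValueError("active population is empty")
    if sc < na:
        raise ValueError(f"clone size {sc} < active size {na}: quotas of 1 impossible")
    d = crowding_distance(_objective_matrix(active))
    finite = d[np.isfinite(d)]
    cap = 2.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
    d = np.where(np.isfinite(d), d, cap)
    if d.sum() == 0:
        d = np.ones(na)
    ideal = sc * d / d.sum()
    q = np.floor(ideal).astype(int)
    q = np.maximum(q, 1)
    # largest-remainder top-up / deterministic trim back to exactly sc
    while q.sum() < sc:
        rem = ideal - q
        q[int(np.argmax(rem))] += 1
    while q.sum() > sc:
        rem = ideal - q
        over = np.flatnonzero(q > 1)
        q[over[int(np.argmin(rem[over]))]] -= 1
    clones: list[Individual] = []
    for ind, cnt in zip(active, q.tolist()):
        clones.extend(ind.copy() for _ in range(cnt))
    return clones


def one_way_crossover(
    parent_a: Individual, parent_b: Individual, rng: np.random.Generator
) -> Individual:
    """Transplant one source community into the other parent.

    A fair coin picks the source parent; a uniformly random node v is
    chosen; every destination node whose *source* label equals v's source
    label receives that label.  Parents are left untouched.
    """
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length")
    if rng.random() < 0.5:
        src, dst = parent_a, parent_b
    else:
        src, dst = parent_b, parent_a
    v = int(rng.integers(len(src)))
    child = dst.labels.copy()
    child[src.labels == src.labels[v]] = src.labels[v]
    return Individual(child)


def neighbor_mutation(
    ind: Individual, g: Graph, p_m: float, rng: np.random.Generator
) -> Individual:
    """Per node, with probability p_m, adopt a uniformly chosen neighbor's label.

    Labels are read from the pre-mutation state (synchronous read,
    sequential write), so the outcome does not depend on node order.
    Isolated nodes are never mutated.
    """
    if not 0.0 <= p_m <= 1.0:
        raise ValueError("mutation probability must lie in [0, 1]")
    old = ind.labels
    new = old.copy()
    hits = np.flatnonzero(rng.random(len(ind)) < p_m)
    for v in hits.tolist():
        nb = g.neighbors[v]
        if nb:
            new[v] = old[nb[int(rng.integers(len(nb)))]]
    return Individual(new)
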