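"""Pseudonormal-vector scalarization and label-propagation local search.

Each nondominated individual is refined along its own search direction in
objective space: a weight vector perpendicular to the secant through its two
nearest front neighbors (the "pseudonormal" vector), which approximates the
front's normal direction.  Boundary members push straight along one axis,
(1,0) for the IntraQ extreme and (0,1) for the InterQ extreme.  The refined
fitness

    S(X) = w1 * IntraQ + w2 * InterQ

is maximized by iterated single-node label updates: each node moves to the
adjacent community (its own included) with maximal fitness increment

    dS_i = (1/m) * [ w1 * e(i, C) - w2 * k_i * K_C / (2m) ]

where e(i, C) counts i's edges into C and K_C sums the degrees of C's
members other than i.  With w = (0.5, 0.5), S = (Q + 1)/2 and the procedure
is exactly the modularity-specialized label propagation algorithm (LPAm).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .encoding import Individual
from .evolution import nondominated_filter
from .graph_core import Graph
from .objectives import ObjectivePoint, evaluate

__all__ = [
    "WeightVector",
    "pseudonormal_vector",
    "scalarized_fitness",
    "delta_fitness",
    "update_node_label",
    "local_search_individual",
    "local_search_population",
]

_HALF = None  # set below once WeightVector exists


class WeightVector(NamedTuple):
    """Nonnegative objective weights summing to 1 (w1 on IntraQ, w2 on InterQ)."""

    w1: float
    w2: float

    def validate(self) -> "WeightVector":
        if self.w1 < 0 or self.w2 < 0 or abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValueError(f"invalid weight vector {self}")
        return self


_HALF = WeightVector(0.5, 0.5)


def pseudonormal_vector(
    front: Sequence[ObjectivePoint], idx: int
) -> WeightVector:
    """Search direction for member ``idx`` of a nondominated front.

    The front must hold mutually nondominated, objective-distinct points.
    Sorted ascending by IntraQ (equivalently descending by InterQ — the
    reversed-order property, asserted here), the member's two sort
    neighbors define the secant; the pseudonormal vector is the unit-sum
    normal to it.  The max-IntraQ boundary gets (1,0), the min-IntraQ
    boundary (0,1); a singleton front falls back to (0.5, 0.5).
    """
    pts = list(front)
    if not 0 <= idx < len(pts):
        raise IndexError("front index out of range")
    if len(pts) == 1:
        return _HALF
    order = sorted(range(len(pts)), key=lambda i: (pts[i].intra, -pts[i].inter))
    inters = [pts[i].inter for i in order]
    if any(inters[i] < inters[i + 1] for i in range(len(inters) - 1)):
        raise ValueError("front violates the reversed-order property (not nondominated?)")
    pos = order.index(idx)
    if pos == len(pts) - 1:  # max-IntraQ boundary
        return WeightVector(1.0, 0.0)
    if pos == 0:  # max-InterQ boundary
        return WeightVector(0.0, 1.0)
    lo, hi = pts[order[pos - 1]], pts[order[pos + 1]]
    df1 = hi.intra - lo.intra
    df2 = lo.inter - hi.inter
    pi = df1 + df2
    if pi <= 0:  # degenerate neighbors (duplicate objectives)
        return _HALF
    return WeightVector(df2 / pi, df1 / pi)


def scalarized_fitness(g: Graph, p, w: WeightVector) -> float:
    """S(X) = w1 * IntraQ + w2 * InterQ."""
    point = evaluate(g, p)
    return w.w1 * point.intra + w.w2 * point.inter


def _candidate_deltas(
    g: Graph, labels: np.ndarray, comm_deg: np.ndarray, v: int, w: WeightVector
) -> dict[int, float]:
    """dS (times m) for every adjacent community of v, its own included."""
    kv = float(g.degrees[v])
    own = int(labels[v])
    edges_to: dict[int, int] = {}
    for u in g.neighbors[v]:
        lab = int(labels[u])
        edges_to[lab] = edges_to.get(lab, 0) + 1
    edges_to.setdefault(own, 0)
    two_m = 2.0 * g.m
    deltas = {}
    for lab, e in edges_to.items():
        k_c = comm_deg[lab] - (kv if lab == own else 0.0)
        deltas[lab] = w.w1 * e - w.w2 * kv * k_c / two_m
    return deltas


def delta_fitness(
    g: Graph, ind: Individual, v: int, target_label: int, w: WeightVector
) -> float:
    """Fitness gain of placing node v, taken as isolated, into the target
    community (which must be adjacent to v, its own community included)."""
    w.validate()
    if g.m == 0:
        raise ValueError("fitness is undefined on an edgeless graph")
    labels = ind.labels
    comm_deg = np.bincount(labels, weights=g.degrees, minlength=int(labels.max()) + 1)
    deltas = _candidate_deltas(g, labels, comm_deg, v, w)
    if target_label not in deltas:
        raise ValueError(f"community {target_label} is not adjacent to node {v}")
    return deltas[target_label] / g.m


def update_node_label(
    g: Graph, ind: Individual, v: int, w: WeightVector, rng: np.random.Generator
) -> tuple[Individual, bool]:
    """Move v to the adjacent community with maximal fitness increment.

    Ties that include the current label keep the current label; other exact
    ties break uniformly at random.  Returns (updated copy, changed).
    """
    labels = ind.labels.copy()
    comm_deg = np.bincount(labels, weights=g.degrees, minlength=int(labels.max()) + 1)
    new = _best_label(g, labels, comm_deg, v, w, rng)
    changed = new != int(labels[v])
    if changed:
        labels[v] = new
    return Individual(labels), changed


def _best_label(
    g: Graph,
    labels: np.ndarray,
    comm_deg: np.ndarray,
    v: int,
    w: WeightVector,
    rng: np.random.Generator,
) -> int:
    deltas = _candidate_deltas(g, labels, comm_deg, v, w)
    own = int(labels[v])
    best = max(deltas.values())
    if deltas[own] == best:
        return own
    winners = [lab for lab, d in deltas.items() if d == best]
    if len(winners) == 1:
        return winners[0]
    return winners[int(rng.integers(len(winners)))]


def local_search_individual(
    g: Graph, ind: Individual, w: WeightVector, mi: int, rng: np.random.Generator
) -> Individual:
    """Sweep single-node updates until a sweep changes nothing or ``mi``
    sweeps elapse; each sweep visits all nodes in a fresh random order with
    immediate effect."""
    if mi < 1:
        raise ValueError("iteration cap must be >= 1")
    w.validate()
    labels = ind.labels.copy()
    # labels always stay within [0, n): updates only adopt existing labels
    comm_deg = np.bincount(labels, weights=g.degrees, minlength=g.n).astype(float)
    deg = g.degrees
    for _ in range(mi):
        changed = False
        for v in rng.permutation(g.n).tolist():
            new = _best_label(g, labels, comm_deg, v, w, rng)
            old = int(labels[v])
            if new != old:
                labels[v] = new
                comm_deg[old] -= deg[v]
                comm_deg[new] += deg[v]
                changed = True
        if not changed:
            break
    return Individual(labels)


def local_search_population(
    pop: Sequence[Individual], g: Graph, mi: int, rng: np.random.Generator
) -> list[Individual]:
    """Refine the nondominated members of a population.

    Dominated members are discarded.  Duplicates (by canonical form or by
    objective point) collapse before the front is built, so the secant
    construction never sees coincident neighbors; each survivor is then
    refined with its own pseudonormal vector, duplicates receiving a copy
    of their representative's refinement.
    """
    nd = nondominated_filter(pop)
    if not nd:
        return []
    reps: list[Individual] = []
    seen_keys: dict[bytes, int] = {}
    seen_pts: dict[tuple[float, float], int] = {}
    rep_of: list[int] = []
    for ind in nd:
        key = ind.canonical_key()
        pt = ind.objectives.as_tuple()
        if key in seen_keys:
            rep_of.append(seen_keys[key])
        elif pt in seen_pts:
            rep_of.append(seen_pts[pt])
        else:
            seen_keys[key] = seen_pts[pt] = len(reps)
            rep_of.append(len(reps))
            reps.append(ind)
    front = [ind.objectives for ind in reps]
    refined = [
        local_search_individual(g, ind, pseudonormal_vector(front, i), mi, rng)
        for i, ind in enumerate(reps)
    ]
    return [refined[r].copy() for r in rep_of]
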