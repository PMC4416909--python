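"""Group-based partition encoding.

An individual is a length-n vector of community labels; nodes sharing a
label form a community.  Any bijective relabeling encodes the same
partition, so a canonical first-appearance renumbering is used for
deduplication and equality.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .graph_core import Graph

__all__ = ["Individual", "PartitionView", "decode", "canonical_form", "init_population"]


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 0,1,2,... in order of first appearance."""
    out = np.empty_like(labels)
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels.tolist()):
        out[i] = seen.setdefault(lab, len(seen))
    return out


class PartitionView:
    """Read-only grouping of node indices by community.

    ``labels`` is stored in canonical form (0-based, first-appearance
    order); ``communities`` lists member-index arrays, ``k`` counts the
    non-empty communities.
    """

    def __init__(self, labels: Sequence[int] | np.ndarray):
        labels = np.asarray(labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d sequence")
        self.labels = _canonical_labels(labels)
        self.labels.flags.writeable = False
        self.k = int(self.labels.max()) + 1

    @property
    def communities(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == c) for c in range(self.k)]

    @property
    def n(self) -> int:
        return self.labels.size

    def __eq__(self, other) -> bool:
        return isinstance(other, PartitionView) and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PartitionView(k={self.k}, n={self.n})"


class Individual:
    """Community-label vector, the unit of evolution.

    Objective values are cached on the instance (``objectives``) and must be
    invalidated whenever ``labels`` is modified in place; operators that
    rewrite labels return fresh instances instead.
    """

    __slots__ = ("labels", "objectives")

    def __init__(self, labels: Sequence[int] | np.ndarray):
        self.labels = np.asarray(labels, dtype=np.int64).copy()
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d sequence")
        self.objectives = None

    def copy(self) -> "Individual":
        ind = Individual(self.labels)
        ind.objectives = self.objectives
        return ind

    def invalidate(self) -> None:
        self.objectives = None

    def decode(self) -> PartitionView:
        return PartitionView(self.labels)

    def canonical(self) -> "Individual":
        return Individual(_canonical_labels(self.labels))

    def canonical_key(self) -> bytes:
        return _canonical_labels(self.labels).tobytes()

    def __len__(self) -> int:
        return self.labels.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Individual(n={len(self)}, k={len(np.unique(self.labels))})"


def decode(ind: Individual) -> PartitionView:
    """Group nodes sharing a community label into communities."""
    return ind.decode()


def canonical_form(ind: Individual) -> Individual:
    """Return the individual with labels renumbered by first appearance.

    Two individuals encode the same partition iff their canonical forms
    carry equal label vectors.
    """
    return ind.canonical()


def init_population(
    g: "Graph", size: int, alpha: float, rng: np.random.Generator
) -> list[Individual]:
    """Heuristic population initialization.

    Every individual starts as all singletons (node i alone in community i).
    Then, for the first floor(alpha * n) nodes of an independent uniform
    permutation, the node's *current* label overwrites all of its
    neighbors' labels, sequentially, so later spreaders can overwrite
    earlier assignments.  alpha = 0.3 is the experimental default.
    """
    if size < 1:
        raise ValueError("population size must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n = g.n
    n_spread = int(math.floor(alpha * n))
    pop: list[Individual] = []
    for _ in range(size):
        labels = np.arange(n, dtype=np.int64)
        order = rng.permutation(n)
        for v in order[:n_spread].tolist():
            nb = g.neighbors[v]
            if nb:
                labels[nb] = labels[v]
        pop.append(Individual(labels))
    return pop
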