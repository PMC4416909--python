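"""Objective functions: the two modularity terms, modularity itself, and NMI.

Modularity Q = sum_C [ l_C/m - (k_C/2m)^2 ] splits into two conflicting
objectives: the intra-community edge fraction

    IntraQ = sum_C l_C / m                  in [0, 1]

favouring few large communities, and the (shifted) degree-penalty term

    InterQ = 1 - sum_C (k_C / 2m)^2         in [0, 1)

favouring many small communities.  Q = IntraQ + InterQ - 1 exactly.
Partition similarity is scored with normalized mutual information in the
confusion-matrix form of Danon et al. (natural logarithms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .encoding import Individual, PartitionView
from .graph_core import Graph

__all__ = ["ObjectivePoint", "evaluate", "intra_q", "inter_q", "modularity", "nmi"]

PartitionLike = Union[Individual, PartitionView]


@dataclass(frozen=True)
class ObjectivePoint:
    """(IntraQ, InterQ) pair; Q is derived."""

    intra: float
    inter: float

    @property
    def q(self) -> float:
        return self.intra + self.inter - 1.0

    def as_tuple(self) -> tuple[float, float]:
        return (self.intra, self.inter)


def _labels_of(p: PartitionLike) -> np.ndarray:
    if isinstance(p, Individual):
        return p.labels
    if isinstance(p, PartitionView):
        return p.labels
    raise TypeError(f"expected Individual or PartitionView, got {type(p)!r}")


def evaluate(g: Graph, p: PartitionLike) -> ObjectivePoint:
    """Compute (IntraQ, InterQ); cached on Individuals."""
    if isinstance(p, Individual) and p.objectives is not None:
        return p.objectives
    if g.m == 0:
        raise ValueError("objectives are undefined on an edgeless graph (m = 0)")
    labels = _labels_of(p)
    if labels.size != g.n:
        raise ValueError("partition length does not match graph size")
    same = labels[g.edges[:, 0]] == labels[g.edges[:, 1]]
    intra = float(np.count_nonzero(same)) / g.m
    k_c = np.bincount(labels, weights=g.degrees)
    inter = 1.0 - float(np.sum((k_c / (2.0 * g.m)) ** 2))
    point = ObjectivePoint(intra, inter)
    if isinstance(p, Individual):
        p.objectives = point
    return point


def intra_q(g: Graph, p: PartitionLike) -> float:
    """Fraction of edges internal to communities, sum_C l_C / m."""
    return evaluate(g, p).intra


def inter_q(g: Graph, p: PartitionLike) -> float:
    """1 - sum_C (k_C / 2m)^2."""
    return evaluate(g, p).inter


def modularity(g: Graph, p: PartitionLike) -> float:
    """Newman-Girvan modularity, equal to IntraQ + InterQ - 1."""
    return evaluate(g, p).q


def nmi(p1: PartitionLike, p2: PartitionLike) -> float:
    """Normalized mutual information between two partitions of one node set.

    Confusion-matrix form with natural logarithms:

        NMI = -2 sum_ij N_ij ln(N_ij N / (N_i N_j))
              / [ sum_i N_i ln(N_i/N) + sum_j N_j ln(N_j/N) ]

    with 0 ln 0 := 0.  Equals 1 iff the partitions coincide up to
    relabeling; a comparison against the single-community partition gives 0.
    """
    a = _labels_of(p1)
    b = _labels_of(p2)
    if a.size != b.size:
        raise ValueError("partitions cover different node sets")
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    conf = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb).astype(float)
    n = float(a.size)
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    nz = conf > 0
    num = -2.0 * np.sum(conf[nz] * np.log(conf[nz] * n / np.outer(row, col)[nz]))
    h = np.sum(row[row > 0] * np.log(row[row > 0] / n)) + np.sum(
        col[col > 0] * np.log(col[col > 0] / n)
    )
    if h == 0.0:
        # both partitions trivial: identical iff both are single-community
        return 1.0 if ka == kb == 1 else 0.0
    return float(num / h)
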