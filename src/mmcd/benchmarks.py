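"""Planted-partition benchmark generators and the repeated-run harness.

Two families of synthetic test networks with known community structure:

* GN benchmark: 128 nodes in four planted communities of 32.  Every node
  has expected degree 16, a fraction 1 - mu of it inside its community.
  Pairs are joined independently (planted l-partition / stochastic block
  model) with p_in = 16(1 - mu)/31 and p_out = 16 mu / 96, so expected
  intra- and inter-degrees are 16(1 - mu) and 16 mu.

* Hierarchical GN benchmark: 256 nodes in 16 level-1 communities of 16,
  nested four-per-supercommunity into 4 level-2 communities.  Expected
  edges per node: 10 to its level-1 community, 5 to the three sibling
  level-1 communities, 2 to the rest — Bernoulli pair probabilities
  10/15, 5/48 and 2/192.

An LFR-format reader maps externally generated heterogeneous benchmarks
(edge list plus node-community membership file) onto the same containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .encoding import Individual, PartitionView
from .graph_core import Graph, load_edge_list, load_truth_partition
from .objectives import evaluate, nmi

__all__ = [
    "GNSpec",
    "HierGNSpec",
    "BenchmarkTruth",
    "generate_gn",
    "generate_hier_gn",
    "load_lfr",
    "evaluate_runs",
]


@dataclass(frozen=True)
class GNSpec:
    n: int = 128
    communities: int = 4
    degree: float = 16.0

    @property
    def community_size(self) -> int:
        return self.n // self.communities


@dataclass(frozen=True)
class HierGNSpec:
    n: int = 256
    level1_communities: int = 16
    level2_communities: int = 4
    # expected per-node edge counts: own level-1, sibling level-1s, rest
    z: tuple[float, float, float] = (10.0, 5.0, 2.0)

    @property
    def level1_size(self) -> int:
        return self.n // self.level1_communities


@dataclass
class BenchmarkTruth:
    """Planted partition(s); one view per hierarchy level, finest first."""

    levels: list[PartitionView] = field(default_factory=list)

    @property
    def partition(self) -> PartitionView:
        return self.levels[0]


def _subseed(rng: np.random.Generator) -> int:
    # networkx generators take python-random seeds, not numpy Generators
    return int(rng.integers(2**31))


def generate_gn(mu: float, rng: np.random.Generator, spec: GNSpec = GNSpec()) -> tuple[Graph, BenchmarkTruth]:
    """Planted four-community benchmark at mixing parameter mu."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mixing parameter must lie in [0, 1]")
    size = spec.community_size
    p_in = spec.degree * (1.0 - mu) / (size - 1)
    p_out = spec.degree * mu / (spec.n - size)
    gnx = nx.planted_partition_graph(
        spec.communities, size, min(p_in, 1.0), min(p_out, 1.0), seed=_subseed(rng)
    )
    g = Graph.from_networkx(gnx)
    labels = np.repeat(np.arange(spec.communities), size)
    return g, BenchmarkTruth(levels=[PartitionView(labels)])


def generate_hier_gn(
    rng: np.random.Generator, spec: HierGNSpec = HierGNSpec()
) -> tuple[Graph, BenchmarkTruth]:
    """Two-level nested benchmark; truths for both levels, finest first."""
    size = spec.level1_size
    n_l1 = spec.level1_communities
    per_super = n_l1 // spec.level2_communities
    z1, z2, z3 = spec.z
    p1 = z1 / (size - 1)
    p2 = z2 / ((per_super - 1) * size)
    p3 = z3 / (spec.n - per_super * size)
    level1 = np.repeat(np.arange(n_l1), size)
    level2 = level1 // per_super
    probs = np.full((n_l1, n_l1), p3)
    for a in range(n_l1):
        for b in range(n_l1):
            if a == b:
                probs[a, b] = p1
            elif a // per_super == b // per_super:
                probs[a, b] = p2
    gnx = nx.stochastic_block_model([size] * n_l1, probs.tolist(), seed=_subseed(rng))
    g = Graph.from_networkx(nx.Graph(gnx))
    return g, BenchmarkTruth(levels=[PartitionView(level1), PartitionView(level2)])


def load_lfr(edge_file, membership_file) -> tuple[Graph, BenchmarkTruth]:
    """Read an externally generated LFR benchmark (edge list + membership)."""
    g = load_edge_list(edge_file)
    truth = load_truth_partition(membership_file, g)
    return g, BenchmarkTruth(levels=[truth])


def evaluate_runs(
    g: Graph,
    partitions: Sequence[Individual | PartitionView],
    truth: Optional[PartitionView] = None,
) -> pd.DataFrame:
    """Max / mean / sample-std summary of per-run selected partitions.

    One row per statistic, one column per metric (Q, and NMI when a ground
    truth is given) — the layout used to compare repeated stochastic runs.
    """
    if not partitions:
        raise ValueError("need at least one run")
    data = {"Q": [evaluate(g, p).q for p in partitions]}
    if truth is not None:
        data["NMI"] = [nmi(p, truth) for p in partitions]
    df = pd.DataFrame(data)
    summary = pd.DataFrame(
        {
            col: {
                "max": df[col].max(),
                "mean": df[col].mean(),
                "std": df[col].std(ddof=1) if len(df) > 1 else 0.0,
            }
            for col in df.columns
        }
    )
    return summary
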