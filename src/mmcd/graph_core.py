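"""Graph container and text I/O.

Networks are undirected, unweighted simple graphs.  Nodes are stored under
0-based contiguous internal indices; the original labels from an input file
are preserved in an id-map so partitions can be written back in the caller's
vocabulary.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .encoding import PartitionView

__all__ = [
    "Graph",
    "GraphFormatError",
    "load_edge_list",
    "load_gml",
    "load_truth_partition",
    "write_edge_list",
    "write_partition",
    "karate_club",
]


class GraphFormatError(ValueError):
    """Raised for malformed edge-list or partition input."""


class Graph:
    """Undirected simple graph.

    Parameters
    ----------
    edges : (m, 2) integer array of internal endpoint indices, deduplicated.
    n : node count; must cover every index in ``edges``.
    node_ids : original node labels, position = internal index.  Defaults to
        ``0..n-1``.
    """

    def __init__(self, edges: np.ndarray, n: int, node_ids: Sequence | None = None):
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if n < 1:
            raise ValueError("graph needs at least one node")
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge endpoint outside [0, n)")
        if edges.size and np.any(edges[:, 0] == edges[:, 1]):
            raise GraphFormatError("self-loops are not allowed")
        # canonical undirected storage: low index first, unique rows
        lo = edges.min(axis=1)
        hi = edges.max(axis=1)
        edges = np.unique(np.column_stack([lo, hi]), axis=0) if edges.size else edges
        self.edges = edges
        self.n = int(n)
        self.m = int(edges.shape[0])
        self.node_ids = list(node_ids) if node_ids is not None else list(range(n))
        if len(self.node_ids) != self.n:
            raise ValueError("node_ids length must equal n")
        self._index = {str(lab): i for i, lab in enumerate(self.node_ids)}
        deg = np.zeros(self.n, dtype=np.int64)
        if self.m:
            np.add.at(deg, edges[:, 0], 1)
            np.add.at(deg, edges[:, 1], 1)
        self.degrees = deg
        # neighbor lists as plain python lists: fast to iterate in sweeps
        nbrs: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in edges.tolist():
            nbrs[u].append(v)
            nbrs[v].append(u)
        self.neighbors = nbrs

    # -- lookups ---------------------------------------------------------

    def index_of(self, label) -> int:
        """Internal index for an original node label (string-normalized)."""
        key = str(label)
        if key not in self._index:
            raise KeyError(f"unknown node label {label!r}")
        return self._index[key]

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix (small graphs / tests only)."""
        A = np.zeros((self.n, self.n), dtype=bool)
        if self.m:
            A[self.edges[:, 0], self.edges[:, 1]] = True
            A[self.edges[:, 1], self.edges[:, 0]] = True
        return A

    # -- conversions -----------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], *, context: Sequence[str] | None = None) -> "Graph":
        """Build from an iterable of (label, label) endpoint pairs.

        ``context`` optionally carries the source line per pair for
        diagnostics.
        """
        ids: dict[str, int] = {}
        labels: list = []
        idx_pairs: list[tuple[int, int]] = []
        for k, (a, b) in enumerate(pairs):
            ka, kb = str(a), str(b)
            if ka == kb:
                where = f" at line {context[k]!r}" if context is not None else ""
                raise GraphFormatError(f"self-loop on node {a!r}{where}")
            for lab, key in ((a, ka), (b, kb)):
                if key not in ids:
                    ids[key] = len(labels)
                    labels.append(lab)
            idx_pairs.append((ids[ka], ids[kb]))
        if not idx_pairs:
            raise GraphFormatError("empty input: no edges found")
        return cls(np.array(idx_pairs), n=len(labels), node_ids=labels)

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        nodes = list(g.nodes())
        pos = {v: i for i, v in enumerate(nodes)}
        edges = [(pos[u], pos[v]) for u, v in g.edges() if u != v]
        if not nodes:
            raise ValueError("empty networkx graph")
        arr = np.array(edges, dtype=np.int64) if edges else np.empty((0, 2), dtype=np.int64)
        return cls(arr, n=len(nodes), node_ids=nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges.tolist()))
        return g


def _open(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r")
    return source


def load_edge_list(source, dialect: str = "whitespace", force_unweighted: bool = False) -> Graph:
    """Read an undirected edge list.

    ``dialect`` is ``"whitespace"`` or ``"csv"``.  Lines starting with ``#``
    and blank lines are skipped.  Duplicate and reversed-duplicate edges
    collapse.  A third numeric column marks a weighted input, which is
    rejected unless ``force_unweighted`` coerces every weight to 1.
    """
    if dialect not in ("whitespace", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh = _open(source)
    pairs: list[tuple] = []
    context: list[str] = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = [t.strip() for t in line.split(",")] if dialect == "csv" else line.split()
        tokens = [t for t in tokens if t]
        if len(tokens) < 2:
            raise GraphFormatError(f"line {lineno}: expected two endpoints, got {line!r}")
        if len(tokens) > 2 and not force_unweighted:
            raise GraphFormatError(
                f"line {lineno}: extra columns (weighted input?); "
                "pass force_unweighted to coerce all weights to 1"
            )
        pairs.append((tokens[0], tokens[1]))
        context.append(f"{lineno}: {line}")
    if isinstance(source, (str, Path)):
        fh.close()
    return Graph.from_pairs(pairs, context=context)


def load_gml(path) -> Graph:
    """Read a standard GML network (via networkx)."""
    import networkx as nx

    return Graph.from_networkx(nx.Graph(nx.read_gml(str(path))))


def write_edge_list(graph: Graph, target) -> None:
    """Write the graph back as a whitespace edge list using original labels."""
    fh = open(target, "w") if isinstance(target, (str, Path)) else target
    for u, v in graph.edges.tolist():
        fh.write(f"{graph.node_ids[u]} {graph.node_ids[v]}\n")
    if isinstance(target, (str, Path)):
        fh.close()


def load_truth_partition(source, graph: Graph) -> PartitionView:
    """Read a two-column ``node community`` file covering every graph node."""
    fh = _open(source)
    assignment: dict[int, str] = {}
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise GraphFormatError(f"line {lineno}: expected 'node community', got {line!r}")
        try:
            idx = graph.index_of(tokens[0])
        except KeyError:
            raise GraphFormatError(f"line {lineno}: node {tokens[0]!r} is not in the graph")
        if idx in assignment:
            raise GraphFormatError(f"line {lineno}: node {tokens[0]!r} assigned twice")
        assignment[idx] = tokens[1]
    if isinstance(source, (str, Path)):
        fh.close()
    missing = [graph.node_ids[i] for i in range(graph.n) if i not in assignment]
    if missing:
        raise GraphFormatError(f"partition file misses nodes: {missing}")
    comm_ids: dict[str, int] = {}
    labels = np.empty(graph.n, dtype=np.int64)
    for i in range(graph.n):
        c = assignment[i]
        labels[i] = comm_ids.setdefault(c, len(comm_ids))
    return PartitionView(labels)


def write_partition(view: PartitionView, graph: Graph, target) -> None:
    """Write a partition as two-column ``node community`` text."""
    fh = open(target, "w") if isinstance(target, (str, Path)) else target
    for i, lab in enumerate(view.labels.tolist()):
        fh.write(f"{graph.node_ids[i]} {lab + 1}\n")
    if isinstance(target, (str, Path)):
        fh.close()


def karate_club() -> tuple[Graph, PartitionView]:
    """Bundled Zachary karate club network with its two-faction split."""
    edges = resources.files("mmcd.data").joinpath("karate.edges").read_text()
    truth = resources.files("mmcd.data").joinpath("karate_factions.truth").read_text()
    g = load_edge_list(io.StringIO(edges))
    t = load_truth_partition(io.StringIO(truth), g)
    return g, t
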