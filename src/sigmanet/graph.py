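"""Graph and partition containers with Matrix Market / edge-list I/O.

Graphs are undirected and possibly weighted.  The adjacency matrix is kept
as a symmetric ``scipy.sparse.csr_array``; a self-loop of input weight ``w``
is stored as ``2w`` on the diagonal so that the weighted degree is a plain
row sum (self-loops count twice toward the degree, and the total degree
mass ``2m`` equals the sum of all adjacency entries).  Node labels from the
input file are preserved for output; internally nodes are 0..n-1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Graph",
    "DegreeVector",
    "Partition",
    "GraphFormatError",
    "read_graph",
    "degree_vector",
    "check_connected",
    "largest_component",
    "read_partition",
    "write_partition",
    "write_graph",
]


class GraphFormatError(ValueError):
    """Raised for unparseable or invalid graph/partition input."""


@dataclass(frozen=True)
class Graph:
    """An undirected weighted graph.

    Parameters
    ----------
    adjacency : scipy.sparse.csr_array
        Symmetric nonnegative weight matrix.  Diagonal entries hold twice
        the self-loop weight (see module docstring).
    node_ids : numpy.ndarray
        Original node labels, index ``i`` holding the label of internal
        node ``i``.
    """

    adjacency: sp.csr_array
    node_ids: np.ndarray

    def __post_init__(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] < 1:
            raise GraphFormatError("adjacency must be square and non-empty")
        if a.nnz and a.data.min() < 0:
            raise GraphFormatError("negative edge weight")
        asym = abs(a - a.T)
        if asym.nnz and asym.max() > 1e-12 * max(1.0, abs(a).max()):
            raise GraphFormatError("adjacency must be symmetric")
        if len(self.node_ids) != a.shape[0]:
            raise GraphFormatError("node_ids length mismatch")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of stored undirected edges (self-loops count once)."""
        a = sp.triu(sp.coo_array(self.adjacency))
        return int(a.nnz)

    @classmethod
    def from_edges(cls, u, v, w=None, node_ids=None, n=None) -> "Graph":
        """Build a graph from half-open edge records.

        Each record ``(u, v, w)`` contributes ``w`` to both ``A[u, v]`` and
        ``A[v, u]``; duplicates accumulate.  A self-loop record therefore
        lands as ``2w`` on the diagonal, matching the storage convention.
        """
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        w = np.ones(len(u)) if w is None else np.asarray(w, dtype=float)
        if n is None:
            n = int(max(u.max(initial=-1), v.max(initial=-1)) + 1)
        if len(u) == 0:
            raise GraphFormatError("empty graph: no edges")
        if w.min() < 0:
            raise GraphFormatError("negative edge weight")
        a = sp.coo_array(
            (np.concatenate([w, w]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(n, n),
        ).tocsr()
        a.sum_duplicates()
        if node_ids is None:
            node_ids = np.arange(n)
        return cls(a, np.asarray(node_ids))

    def subgraph(self, nodes: np.ndarray) -> "Graph":
        nodes = np.asarray(nodes)
        a = self.adjacency[np.ix_(nodes, nodes)]
        return Graph(sp.csr_array(a), self.node_ids[nodes])


@dataclass(frozen=True)
class DegreeVector:
    """Weighted degrees ``k`` and total degree mass ``2m = sum(k)``."""

    k: np.ndarray
    two_m: float


@dataclass(frozen=True)
class Partition:
    """A node -> community labelling over internal node indices 0..n-1."""

    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def relabel(self) -> "Partition":
        """Canonical labels: communities numbered by first appearance."""
        _, inv = np.unique(self.labels, return_inverse=True)
        order = {}
        out = np.empty_like(inv)
        for i, c in enumerate(inv):
            out[i] = order.setdefault(int(c), len(order))
        return Partition(out)


def degree_vector(g: Graph) -> DegreeVector:
    """Row sums of the adjacency and their total ``2m``."""
    k = np.asarray(g.adjacency.sum(axis=1)).ravel()
    return DegreeVector(k=k, two_m=float(k.sum()))


def _parse_edgelist(text: str, path: str) -> Graph:
    us, vs, ws = [], [], []
    labels: dict[str, int] = {}

    def idx(tok: str) -> int:
        return labels.setdefault(tok, len(labels))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line[0] in "#%":
            continue
        parts = line.replace(",", " ").split()
        if len(parts) not in (2, 3):
            raise GraphFormatError(f"{path}:{lineno}: expected 'u v [w]', got {raw!r}")
        try:
            w = float(parts[2]) if len(parts) == 3 else 1.0
        except ValueError:
            raise GraphFormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from None
        if w < 0:
            raise GraphFormatError(f"{path}:{lineno}: negative weight {w}")
        us.append(idx(parts[0]))
        vs.append(idx(parts[1]))
        ws.append(w)
    if not us:
        raise GraphFormatError(f"{path}: no edges found")
    ids = np.array(list(labels.keys()))
    # sort node ids numerically when they all parse as integers
    try:
        order = np.argsort(ids.astype(np.int64), kind="stable")
    except ValueError:
        order = np.argsort(ids, kind="stable")
    rank = np.empty(len(ids), dtype=np.int64)
    rank[order] = np.arange(len(ids))
    u = rank[np.asarray(us)]
    v = rank[np.asarray(vs)]
    return Graph.from_edges(u, v, ws, node_ids=ids[order], n=len(ids))


def _read_mtx(path) -> Graph:
    m = scipy.io.mmread(path)
    m = sp.coo_array(m)
    if m.shape[0] != m.shape[1]:
        raise GraphFormatError(f"{path}: matrix is not square")
    csr = sp.csr_array(m)
    csr.sum_duplicates()
    asym = abs(csr - csr.T)
    if asym.nnz and asym.max() > 1e-12 * max(1.0, abs(csr).max()):
        csr = csr + csr.T  # general file listing each edge once
    if csr.nnz == 0:
        raise GraphFormatError(f"{path}: no edges found")
    if csr.data.min() < 0:
        raise GraphFormatError(f"{path}: negative edge weight")
    # store self-loops doubled (mtx stores the plain loop weight once)
    d = csr.diagonal()
    if d.any():
        csr = csr + sp.diags_array(d).tocsr()
    return Graph(csr, np.arange(1, csr.shape[0] + 1))


def read_graph(path, fmt: str = "auto") -> Graph:
    """Read a graph from a Matrix Market file or a plain edge list.

    ``fmt`` is ``"mtx"``, ``"edgelist"``, or ``"auto"`` (sniff: a
    ``%%MatrixMarket`` banner selects mtx).  The returned graph is
    symmetric with duplicate edge weights summed; original node labels
    are preserved in ``node_ids`` (1-based for mtx input).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if fmt == "auto":
        fmt = "mtx" if text.lstrip().startswith("%%MatrixMarket") else "edgelist"
    if fmt == "mtx":
        return _read_mtx(io.StringIO(text))
    if fmt == "edgelist":
        return _parse_edgelist(text, str(path))
    raise ValueError(f"unknown format {fmt!r}")


def write_graph(g: Graph, path) -> None:
    """Write as Matrix Market coordinate symmetric (lower triangle).

    Diagonal entries are halved on output so that read/write round-trips
    under the doubled self-loop storage convention.
    """
    a = sp.coo_array(sp.tril(g.adjacency)).copy()
    mask = a.row == a.col
    a.data[mask] /= 2.0
    scipy.io.mmwrite(str(path), sp.coo_matrix(a), symmetry="symmetric")


def check_connected(g: Graph) -> bool:
    ncomp, _ = connected_components(g.adjacency, directed=False)
    return ncomp == 1


def largest_component(g: Graph) -> Graph:
    """Subgraph on the largest connected component.

    Ties between equal-size components are broken in favour of the one
    containing the smallest original node id.
    """
    ncomp, lab = connected_components(g.adjacency, directed=False)
    if ncomp == 1:
        return g
    sizes = np.bincount(lab, minlength=ncomp)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # smallest minimum original node id wins
        try:
            ids = g.node_ids.astype(np.int64)
        except ValueError:
            ids = g.node_ids
        mins = [ids[lab == c].min() for c in best]
        best = [best[int(np.argmin(mins))]]
    return g.subgraph(np.flatnonzero(lab == best[0]))


def write_partition(p: Partition, path, node_ids=None) -> None:
    """Write a partition as TSV with header ``node<TAB>community``."""
    ids = np.arange(p.n) if node_ids is None else np.asarray(node_ids)
    with open(path, "w") as fh:
        fh.write("node\tcommunity\n")
        for i in range(p.n):
            fh.write(f"{ids[i]}\t{p.labels[i]}\n")


def read_partition(path, node_ids=None) -> Partition:
    """Read a partition TSV; order-insensitive in the node column.

    When ``node_ids`` is given, every listed node must appear in the file
    and labels are returned in ``node_ids`` order; otherwise nodes are
    sorted (numerically when possible).
    """
    rows: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("node"):
            raise GraphFormatError(f"{path}: missing 'node\\tcommunity' header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphFormatError(f"{path}:{lineno}: expected 'node<TAB>community'")
            rows[parts[0]] = int(parts[1])
    if not rows:
        raise GraphFormatError(f"{path}: empty partition")
    if node_ids is None:
        keys = list(rows)
        try:
            keys.sort(key=int)
        except ValueError:
            keys.sort()
    else:
        keys = [str(i) for i in node_ids]
        missing = [k for k in keys if k not in rows]
        if missing:
            raise GraphFormatError(f"{path}: nodes missing from file: {missing[:5]}")
    return Partition(np.array([rows[k] for k in keys]))
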