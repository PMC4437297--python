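"""Random-network generation, components, fixtures, and initial opinions.

The simulator works on undirected simple graphs with nodes ``0..n-1``,
stored as a symmetric CSR adjacency matrix so that neighbor averages are a
single sparse matrix-vector product.  Erdos-Renyi graphs G(n, p) with
p = <k>/(n-1) are the model's default substrate (Poisson degree
distribution, mean degree <k>).
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NetworkGraph",
    "InitialCondition",
    "generate_er",
    "largest_component",
    "init_opinions",
    "path_graph",
    "star_graph",
    "complete_graph",
    "two_triangles",
    "write_edgelist",
    "read_edgelist",
]


class NetworkGraph:
    """Undirected simple graph backed by a CSR adjacency matrix.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; node ids are ``0..n_nodes-1``.
    edges : array-like of shape (m, 2)
        Unordered node pairs.  Self-loops and duplicate edges are rejected.
    """

    def __init__(self, n_nodes: int, edges: Iterable[Sequence[int]] | np.ndarray):
        n_nodes = int(n_nodes)
        if n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")
        edges = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                           dtype=np.int64)
        if edges.size == 0:
            edges = edges.reshape(0, 2)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be pairs of node ids")
        if edges.size:
            if edges.min() < 0 or edges.max() >= n_nodes:
                raise ValueError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            canon = np.sort(edges, axis=1)
            uniq = np.unique(canon, axis=0)
            if uniq.shape[0] != canon.shape[0]:
                raise ValueError("duplicate edges are not allowed")
            edges = uniq
        self.n_nodes = n_nodes
        self._edges = edges
        row = np.concatenate([edges[:, 0], edges[:, 1]])
        col = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.ones(row.size, dtype=np.float64)
        adj = sp.coo_matrix((data, (row, col)), shape=(n_nodes, n_nodes)).tocsr()
        self._adj = adj
        self._indptr = adj.indptr
        self._indices = adj.indices
        self._indptr64 = adj.indptr.astype(np.int64)
        self._indices64 = adj.indices.astype(np.int64)
        self._degrees = np.diff(adj.indptr).astype(np.int64)
        self._lcc: np.ndarray | None = None

    # ------------------------------------------------------------------ basic
    @property
    def adjacency(self) -> sp.csr_matrix:
        return self._adj

    @property
    def csr64(self) -> tuple:
        """(indptr, indices) as int64 arrays, cached for compiled kernels."""
        return self._indptr64, self._indices64

    @property
    def edges(self) -> np.ndarray:
        """Canonical (sorted, deduplicated) edge array of shape (m, 2)."""
        return self._edges

    @property
    def m_edges(self) -> int:
        return self._edges.shape[0]

    @property
    def mean_degree(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return 2.0 * self.m_edges / self.n_nodes

    @property
    def degrees(self) -> np.ndarray:
        return self._degrees

    def neighbors(self, node: int) -> np.ndarray:
        if not (0 <= node < self.n_nodes):
            raise KeyError(f"unknown node id {node}")
        return self._indices[self._indptr[node]:self._indptr[node + 1]]

    # --------------------------------------------------------- fast gathers
    def _gather_neighbor_cols(self, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated neighbor columns of `nodes` plus per-node counts."""
        starts = self._indptr[nodes]
        counts = self._indptr[nodes + 1] - starts
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=self._indices.dtype), counts
        # vectorised ragged gather: absolute positions into `indices`
        rep_starts = np.repeat(starts, counts)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        return self._indices[rep_starts + offs], counts

    def row_means(self, nodes: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Mean of ``values`` over the neighbors of each node in ``nodes``.

        All nodes must have degree >= 1.
        """
        nodes = np.asarray(nodes, dtype=np.int64)
        if nodes.size == 0:
            return np.empty(0)
        if nodes.size > max(64, self.n_nodes // 4):
            s = self._adj @ values
            return s[nodes] / self._degrees[nodes]
        cols, counts = self._gather_neighbor_cols(nodes)
        sums = np.add.reduceat(values[cols], np.cumsum(counts) - counts)
        return sums / counts

    def neighborhood_closure(self, nodes: np.ndarray) -> np.ndarray:
        """Sorted union of ``nodes`` and all their neighbors."""
        nodes = np.asarray(nodes, dtype=np.int64)
        if nodes.size == 0:
            return nodes
        if nodes.size > max(64, self.n_nodes // 4):
            mask = np.zeros(self.n_nodes, dtype=bool)
            mask[nodes] = True
            reach = (self._adj @ mask.astype(np.float64)) > 0
            return np.flatnonzero(mask | reach)
        cols, _ = self._gather_neighbor_cols(nodes)
        return np.union1d(nodes, cols)

    # ------------------------------------------------------------ components
    def largest_component(self) -> np.ndarray:
        """Node ids of the largest connected component.

        Ties between equally-sized components are broken in favour of the
        component containing the smallest node id.
        """
        if self._lcc is not None:
            return self._lcc
        if self.n_nodes == 0:
            self._lcc = np.empty(0, dtype=np.int64)
            return self._lcc
        _, labels = connected_components(self._adj, directed=False)
        counts = np.bincount(labels)
        best = counts.max()
        cand_labels, first_idx = np.unique(labels, return_index=True)
        mask = counts[cand_labels] == best
        # first_idx is the smallest node id in each label; pick the minimum
        chosen = cand_labels[mask][np.argmin(first_idx[mask])]
        self._lcc = np.flatnonzero(labels == chosen)
        return self._lcc

    @property
    def largest_component_size(self) -> int:
        return int(self.largest_component().size)

    def subgraph(self, nodes: np.ndarray) -> "NetworkGraph":
        """Induced subgraph with nodes relabelled 0..len(nodes)-1 (sorted order)."""
        nodes = np.unique(np.asarray(nodes, dtype=np.int64))
        relabel = -np.ones(self.n_nodes, dtype=np.int64)
        relabel[nodes] = np.arange(nodes.size)
        keep = (relabel[self._edges[:, 0]] >= 0) & (relabel[self._edges[:, 1]] >= 0)
        sub_edges = relabel[self._edges[keep]]
        return NetworkGraph(nodes.size, sub_edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self._edges))
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return (f"NetworkGraph(n={self.n_nodes}, m={self.m_edges}, "
                f"<k>={self.mean_degree:.3f})")


@dataclasses.dataclass(frozen=True)
class InitialCondition:
    """Initial positive fraction f0 and the seed used to realise it."""

    f0: float
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")


def _gnp_edge_positions(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Linear indices of present edges in the upper triangle of G(n, p).

    Vectorised geometric skipping: gaps between successive present pairs in
    the row-major enumeration of the n(n-1)/2 candidate pairs are iid
    Geometric(p), which reproduces independent Bernoulli(p) edges exactly.
    """
    m_max = n * (n - 1) // 2
    if p >= 1.0:
        return np.arange(m_max, dtype=np.int64)
    chunks = []
    pos = np.int64(-1)
    batch = max(1000, int(1.2 * m_max * p) + 10)
    while True:
        gaps = rng.geometric(p, size=batch)
        new = pos + np.cumsum(gaps)
        inside = new < m_max
        chunks.append(new[inside])
        if not inside.all():
            break
        pos = new[-1]
        batch = max(1000, batch // 4)
    return np.concatenate(chunks)


def _positions_to_pairs(t: np.ndarray, n: int) -> np.ndarray:
    """Row-major upper-triangle linear index -> (i, j) node pairs, i < j."""
    b = 2.0 * n - 1.0
    i = np.floor((b - np.sqrt(b * b - 8.0 * t)) / 2.0).astype(np.int64)

    def row_start(i):
        return i * (2 * n - i - 1) // 2

    # one-step float correction
    i -= row_start(i) > t
    i += row_start(i + 1) <= t
    j = i + 1 + (t - row_start(i))
    return np.column_stack([i, j])


def generate_er(n: int, k_mean: float, seed: int) -> NetworkGraph:
    """Erdos-Renyi G(n, p) graph with p = k_mean / (n - 1).

    The realised mean degree fluctuates around ``k_mean`` with standard
    deviation ~ sqrt(2 k_mean / n); it is available as ``graph.mean_degree``.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < k_mean < n:
        raise ValueError("require 0 < k_mean < n")
    p = k_mean / (n - 1)
    rng = np.random.default_rng(seed)
    t = _gnp_edge_positions(n, p, rng)
    return NetworkGraph(n, _positions_to_pairs(t, n))


def largest_component(g: NetworkGraph) -> np.ndarray:
    """Functional alias for :meth:`NetworkGraph.largest_component`."""
    return g.largest_component()


def init_opinions(g: NetworkGraph, ic: InitialCondition) -> "OpinionState":
    """Assign initial opinions: round(f0*n) nodes ~ U(0,1), the rest ~ U(-1,0).

    Exactly ``round(f0 * n)`` distinct nodes (chosen uniformly at random)
    receive positive opinions, which keeps the initial positive count free of
    Bernoulli noise.  Draws of exactly 0 are resampled so every node has a
    definite initial polarity.
    """
    from .model import OpinionState  # local import to avoid a cycle

    rng = np.random.default_rng(ic.seed)
    n = g.n_nodes
    k = int(round(ic.f0 * n))
    perm = rng.permutation(n)
    q = np.empty(n, dtype=np.float64)

    def _nonzero_uniform(size: int) -> np.ndarray:
        u = rng.random(size)
        bad = u == 0.0
        while bad.any():  # pragma: no cover - probability ~2^-53 per draw
            u[bad] = rng.random(int(bad.sum()))
            bad = u == 0.0
        return u

    q[perm[:k]] = _nonzero_uniform(k)
    q[perm[k:]] = -_nonzero_uniform(n - k)
    return OpinionState(opinions=q, network=g)


# ------------------------------------------------------------------ fixtures
def path_graph(n: int) -> NetworkGraph:
    return NetworkGraph(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n: int) -> NetworkGraph:
    """Star with hub 0 and n-1 leaves."""
    return NetworkGraph(n, [(0, i) for i in range(1, n)])


def complete_graph(n: int) -> NetworkGraph:
    return NetworkGraph(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


def two_triangles() -> NetworkGraph:
    """Two disjoint triangles {0,1,2}, {3,4,5} plus isolated node 6."""
    return NetworkGraph(7, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


# ------------------------------------------------------------------- file IO
def write_edgelist(g: NetworkGraph, path) -> None:
    """Two whitespace-separated integer columns; a header comment records n."""
    with open(path, "w") as fh:
        fh.write(f"# nodes {g.n_nodes}\n")
        for u, v in g.edges:
            fh.write(f"{u} {v}\n")


def read_edgelist(path) -> NetworkGraph:
    n = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "nodes":
                    n = int(parts[1])
                continue
            u, v = line.split()
            edges.append((int(u), int(v)))
    if n is None:
        n = 1 + max((max(e) for e in edges), default=-1)
    return NetworkGraph(n, edges)
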