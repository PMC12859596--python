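"""Adjacency structure over small areas.

The spatial units of a small-area analysis enter the model only through
their neighbourhood graph: the intrinsic CAR prior is built from the
degree and adjacency matrices, and nothing downstream consumes
coordinates or polygons.  Real geographies (e.g. English MSOAs) are
supplied as an edge list; synthetic studies use rook-adjacency lattices.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = ["AreaGraph", "make_lattice_graph", "read_edge_list", "write_edge_list"]


@dataclass(frozen=True)
class AreaGraph:
    """Undirected adjacency over ``n_areas`` areas indexed ``0..n_areas-1``.

    Edges are stored as a ``(m, 2)`` integer array with each row sorted
    ``(low, high)`` and rows in lexicographic order.  Self-loops and
    duplicate edges are rejected.
    """

    n_areas: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError(f"n_areas must be positive, got {self.n_areas}")
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n_areas:
                raise ValueError("edge endpoints must lie in [0, n_areas)")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            edges = np.sort(edges, axis=1)
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
            if len(edges) > 1 and np.any(np.all(np.diff(edges, axis=0) == 0, axis=1)):
                raise ValueError("duplicate edges are not allowed")
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix W."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges))
        w = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_areas, self.n_areas),
        )
        return w.tocsr()

    @cached_property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_areas, dtype=np.int64)
        np.add.at(d, self.edges[:, 0], 1)
        np.add.at(d, self.edges[:, 1], 1)
        return d

    @cached_property
    def component_labels(self) -> np.ndarray:
        """Connected-component id per area (0-based, order of discovery)."""
        n, labels = connected_components(self.adjacency, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0


def make_lattice_graph(n_rows: int, n_cols: int) -> AreaGraph:
    """Rook-adjacency grid graph with ``n_rows * n_cols`` areas.

    Cell (r, c) maps to index ``r * n_cols + c``.  The edge count is
    ``n_rows*(n_cols-1) + n_cols*(n_rows-1)`` and the graph is connected.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            k = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((k, k + 1))
            if r + 1 < n_rows:
                edges.append((k, k + n_cols))
    return AreaGraph(n_rows * n_cols, np.asarray(edges, dtype=np.int64).reshape(-1, 2))


def write_edge_list(graph: AreaGraph, path: str | Path) -> None:
    """Write a whitespace-separated edge list with an ``n_areas`` header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"n_areas {graph.n_areas}\n")
        for a, b in graph.edges:
            fh.write(f"{a} {b}\n")


def read_edge_list(path: str | Path) -> AreaGraph:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[0] != "n_areas":
            raise ValueError(f"{path}: expected header 'n_areas <N>', got {header!r}")
        n_areas = int(header[1])
        pairs = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()
            pairs.append((int(a), int(b)))
    return AreaGraph(n_areas, np.asarray(pairs, dtype=np.int64).reshape(-1, 2))
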