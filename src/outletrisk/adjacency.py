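"""Areal adjacency structures for intrinsic CAR priors.

An :class:`AdjacencyStructure` is an undirected graph over areal units
(census block groups here).  It backs both the ICAR prior evaluation in the
model and exact ICAR simulation in the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class AdjacencyError(ValueError):
    """Raised for malformed adjacency input (asymmetry, self-loops...)."""


@dataclass
class AdjacencyStructure:
    """Symmetric neighbor structure over areal units.

    Parameters
    ----------
    ids
        Unit identifiers, in canonical order.
    neighbors
        ``neighbors[i]`` holds the integer indices of the units adjacent to
        unit ``i``.  Must be symmetric and free of self-loops.
    """

    ids: list[str]
    neighbors: list[np.ndarray]

    # derived, filled in __post_init__
    n: int = field(init=False)
    degree: np.ndarray = field(init=False)
    n_islands: int = field(init=False)
    n_components: int = field(init=False)
    component_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n = len(self.ids)
        if self.n == 0:
            raise AdjacencyError("empty adjacency")
        if len(self.neighbors) != self.n:
            raise AdjacencyError("ids and neighbor lists have different lengths")
        self.neighbors = [np.asarray(nb, dtype=np.int64) for nb in self.neighbors]
        nbsets = [set(nb.tolist()) for nb in self.neighbors]
        for i, nb in enumerate(nbsets):
            if i in nb:
                raise AdjacencyError(f"unit {self.ids[i]!r} lists itself as a neighbor")
            for j in nb:
                if j < 0 or j >= self.n:
                    raise AdjacencyError(f"unit {self.ids[i]!r} has out-of-range neighbor index {j}")
                if i not in nbsets[j]:
                    raise AdjacencyError(
                        f"asymmetric adjacency: {self.ids[i]!r} lists {self.ids[j]!r} "
                        "but not vice versa"
                    )
        self.degree = np.array([len(nb) for nb in self.neighbors], dtype=np.int64)
        self.n_islands = int(np.sum(self.degree == 0))
        ncomp, labels = connected_components(self.weight_matrix(), directed=False)
        self.n_components = int(ncomp)
        self.component_labels = labels

    # -- matrices ---------------------------------------------------------

    def weight_matrix(self) -> sp.csr_matrix:
        """0/1 neighbor indicator matrix W (symmetric, zero diagonal)."""
        rows = np.repeat(np.arange(self.n), self.degree)
        cols = np.concatenate(self.neighbors) if self.degree.sum() else np.array([], dtype=np.int64)
        data = np.ones(len(cols))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian L = D - W; the ICAR precision is tau * L."""
        return sp.diags(self.degree.astype(float)) - self.weight_matrix()

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper coloring; same-color units are never adjacent.

        Used for blockwise-parallel single-site Metropolis updates of CAR
        effects.  A rook lattice gets exactly two colors.
        """
        color = np.full(self.n, -1, dtype=np.int64)
        for i in range(self.n):
            used = {color[j] for j in self.neighbors[i] if color[j] >= 0}
            c = 0
            while c in used:
                c += 1
            color[i] = c
        return [np.flatnonzero(color == c) for c in range(color.max() + 1)]

    def index_of(self, unit_id: str) -> int:
        try:
            return self.ids.index(unit_id)
        except ValueError:
            raise KeyError(unit_id) from None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_lattice(cls, rows: int, cols: int, ids: list[str] | None = None) -> "AdjacencyStructure":
        """Rook adjacency on a rows x cols rectangular lattice."""
        if rows * cols < 1:
            raise AdjacencyError("lattice must have at least one cell")
        n = rows * cols
        if ids is None:
            ids = [f"BG{i + 1:05d}" for i in range(n)]
        neighbors: list[np.ndarray] = []
        for r in range(rows):
            for c in range(cols):
                nb = []
                if r > 0:
                    nb.append((r - 1) * cols + c)
                if r < rows - 1:
                    nb.append((r + 1) * cols + c)
                if c > 0:
                    nb.append(r * cols + c - 1)
                if c < cols - 1:
                    nb.append(r * cols + c + 1)
                neighbors.append(np.array(nb, dtype=np.int64))
        return cls(ids=ids, neighbors=neighbors)

    @classmethod
    def from_neighbor_ids(cls, mapping: dict[str, list[str]]) -> "AdjacencyStructure":
        """Build from an ``{id: [neighbor ids]}`` mapping (validated)."""
        ids = list(mapping)
        index = {u: i for i, u in enumerate(ids)}
        neighbors = []
        for u in ids:
            try:
                neighbors.append(np.array([index[v] for v in mapping[u]], dtype=np.int64))
            except KeyError as exc:
                raise AdjacencyError(f"unit {u!r} lists unknown neighbor {exc.args[0]!r}") from None
        return cls(ids=ids, neighbors=neighbors)
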