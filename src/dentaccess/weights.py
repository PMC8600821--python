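"""Contiguity spatial weights.

Rook contiguity: two polygons are neighbours iff they share a boundary
segment of positive length (touching at a single vertex does not count).
Weights can also be built directly from an explicit edge list, which is the
native representation for lattice townships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Hashable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = ["SpatialWeights", "rook_weights"]


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse contiguity structure over a fixed ordering of unit ids.

    Parameters
    ----------
    ids
        Unit identifiers; their order fixes the row/column order of the
        weight matrix.
    neighbors
        ``neighbors[i]`` is the list of *positions* adjacent to position i.
        Must be symmetric and free of self-loops.
    style
        ``"binary"`` (w_ij = 1 for neighbours) or ``"row-standardized"``
        (each non-empty row sums to 1).
    provenance
        Free-form note on how the adjacency was derived.
    """

    ids: tuple[Hashable, ...]
    neighbors: tuple[tuple[int, ...], ...]
    style: str = "binary"
    provenance: str = "explicit-edges"
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("unit ids must be unique")
        if len(self.neighbors) != n:
            raise ValueError("neighbors list length must match ids")
        for i, nbrs in enumerate(self.neighbors):
            if i in nbrs:
                raise ValueError(f"self-neighbor at unit {self.ids[i]!r}")
            for j in nbrs:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")
        if self.style not in ("binary", "row-standardized"):
            raise ValueError(f"unknown style {self.style!r}")
        object.__setattr__(self, "_index", {u: i for i, u in enumerate(self.ids)})

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable]],
        ids: Sequence[Hashable] | None = None,
        style: str = "binary",
    ) -> "SpatialWeights":
        """Build weights from an undirected edge list.

        ``ids`` fixes the unit ordering and may include units that appear in
        no edge (islands); if omitted, ids are the sorted set of edge
        endpoints. Edges are symmetrized; duplicates collapse.
        """
        edges = list(edges)
        if ids is None:
            ids = sorted({u for e in edges for u in e})
        index = {u: i for i, u in enumerate(ids)}
        if len(index) != len(ids):
            raise ValueError("unit ids must be unique")
        adj: list[set[int]] = [set() for _ in ids]
        for a, b in edges:
            if a not in index or b not in index:
                raise KeyError(f"edge ({a!r}, {b!r}) references unknown unit")
            if a == b:
                continue
            adj[index[a]].add(index[b])
            adj[index[b]].add(index[a])
        w = cls(
            ids=tuple(ids),
            neighbors=tuple(tuple(sorted(s)) for s in adj),
            style="binary",
            provenance="explicit-edges",
        )
        return w.row_standardized() if style == "row-standardized" else w

    # -- derived views -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def islands(self) -> tuple[Hashable, ...]:
        return tuple(self.ids[i] for i, nb in enumerate(self.neighbors) if not nb)

    def neighbors_of(self, unit: Hashable) -> tuple[Hashable, ...]:
        return tuple(self.ids[j] for j in self.neighbors[self._index[unit]])

    def row_standardized(self) -> "SpatialWeights":
        if self.style == "row-standardized":
            return self
        return SpatialWeights(
            ids=self.ids,
            neighbors=self.neighbors,
            style="row-standardized",
            provenance=self.provenance,
        )

    def sparse(self) -> sparse.csr_matrix:
        """Weight matrix in the id order (row-standardized rows sum to 1)."""
        rows, cols, vals = [], [], []
        for i, nbrs in enumerate(self.neighbors):
            k = len(nbrs)
            for j in nbrs:
                rows.append(i)
                cols.append(j)
                vals.append(1.0 / k if self.style == "row-standardized" else 1.0)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()

    def binary_adjacency(self) -> sparse.csr_matrix:
        """Underlying symmetric 0/1 adjacency regardless of style."""
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbors):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
        vals = np.ones(len(rows))
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def subset(self, keep: Sequence[Hashable]) -> "SpatialWeights":
        """Restrict to ``keep`` (order preserved); edges leaving the subset drop."""
        keep_idx = [self._index[u] for u in keep]
        remap = {old: new for new, old in enumerate(keep_idx)}
        nbrs = tuple(
            tuple(remap[j] for j in self.neighbors[i] if j in remap) for i in keep_idx
        )
        return SpatialWeights(
            ids=tuple(keep), neighbors=nbrs, style=self.style,
            provenance=self.provenance,
        )


def rook_weights(
    source: Mapping[Hashable, object] | Iterable[tuple[Hashable, Hashable]],
    ids: Sequence[Hashable] | None = None,
    style: str = "binary",
) -> SpatialWeights:
    """Rook-contiguity weights from polygons or an explicit edge list.

    Parameters
    ----------
    source
        Either a mapping ``id -> shapely Polygon`` (neighbours are pairs
        whose intersection has positive length — shared-edge contact; a
        shared corner point does not qualify) or an iterable of
        ``(id_a, id_b)`` edges taken as given after symmetrization.
    ids
        Optional explicit unit ordering (edge-list form only).
    style
        ``"binary"`` or ``"row-standardized"``.
    """
    if isinstance(source, Mapping):
        from shapely.strtree import STRtree

        keys = list(source.keys())
        geoms = [source[k] for k in keys]
        tree = STRtree(geoms)
        edges: list[tuple[Hashable, Hashable]] = []
        for i, g in enumerate(geoms):
            for j in tree.query(g):
                j = int(j)
                if j <= i:
                    continue
                inter = g.intersection(geoms[j])
                if inter.length > 0.0:  # 1-D contact; a point has length 0
                    edges.append((keys[i], keys[j]))
        w = SpatialWeights.from_edges(edges, ids=keys, style=style)
        object.__setattr__(w, "provenance", "rook-from-polygons")
        return w
    return SpatialWeights.from_edges(source, ids=ids, style=style)
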