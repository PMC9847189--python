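"""Spatial contiguity weights for areal units.

Neighborhood adjacency is represented as a symmetric binary contiguity
structure (first-order rook by construction on lattices and polygon
inputs).  The stored neighbor sets never contain the unit itself; the
Getis-Ord Gi* statistic adds self-inclusion (w_ii = 1) explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = ["SpatialWeights", "lattice_rook_weights", "polygon_rook_weights"]


@dataclass
class SpatialWeights:
    """Symmetric binary contiguity weights.

    Parameters
    ----------
    ids
        Ordered unit identifiers.
    neighbors
        Mapping id -> set of adjacent ids.  Must be symmetric and must
        not include self-loops.
    scheme
        ``"binary"`` (the only scheme the pipeline uses) or
        ``"row_standardized"`` for completeness.
    """

    ids: list
    neighbors: dict = field(repr=False)
    scheme: str = "binary"

    def __post_init__(self) -> None:
        idset = set(self.ids)
        if len(idset) != len(self.ids):
            raise ValueError("duplicate unit ids in weights")
        if self.scheme not in ("binary", "row_standardized"):
            raise ValueError(f"unknown weights scheme: {self.scheme!r}")
        for i in self.ids:
            for j in self.neighbors.get(i, ()):
                if j == i:
                    raise ValueError(f"unit {i!r} listed as its own neighbor")
                if j not in idset:
                    raise ValueError(f"neighbor {j!r} of {i!r} is not a unit")
                if i not in self.neighbors.get(j, ()):
                    raise ValueError(
                        f"asymmetric adjacency: {i!r}->{j!r} without {j!r}->{i!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpatialWeights):
            return NotImplemented
        return (
            list(self.ids) == list(other.ids)
            and {i: set(self.neighbors.get(i, set())) for i in self.ids}
            == {i: set(other.neighbors.get(i, set())) for i in other.ids}
            and self.scheme == other.scheme
        )

    @classmethod
    def from_edges(
        cls, ids: Sequence[Hashable], edges: Iterable[tuple], scheme: str = "binary"
    ) -> "SpatialWeights":
        """Build from an undirected edge list; both directions may be listed."""
        nbrs: dict = {i: set() for i in ids}
        for a, b in edges:
            if a not in nbrs or b not in nbrs:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown unit")
            if a == b:
                raise ValueError(f"self-loop on unit {a!r}")
            nbrs[a].add(b)
            nbrs[b].add(a)
        return cls(ids=list(ids), neighbors=nbrs, scheme=scheme)

    def require_symmetric_input(self, edges: Iterable[tuple]) -> None:
        """Validate that an edge list already contains both directions."""
        seen = {(a, b) for a, b in edges}
        missing = [(a, b) for a, b in seen if (b, a) not in seen]
        if missing:
            raise ValueError(f"edge list not symmetric; missing reverses for {missing[:5]}")

    def matrix(self, include_self: bool = True) -> np.ndarray:
        """Dense binary weight matrix in the order of ``ids``."""
        index = {u: k for k, u in enumerate(self.ids)}
        w = np.zeros((self.n, self.n))
        for i in self.ids:
            for j in self.neighbors.get(i, ()):
                w[index[i], index[j]] = 1.0
        if include_self:
            np.fill_diagonal(w, 1.0)
        if self.scheme == "row_standardized":
            rs = w.sum(axis=1, keepdims=True)
            rs[rs == 0] = 1.0
            w = w / rs
        return w

    def edge_list(self) -> list[tuple]:
        """Both-direction edge list, deterministically ordered."""
        out = []
        for i in self.ids:
            for j in sorted(self.neighbors.get(i, ()), key=str):
                out.append((i, j))
        return out


def lattice_rook_weights(
    rows: int, cols: int, torus: bool = False, id_fn=None
) -> SpatialWeights:
    """First-order rook contiguity on a ``rows x cols`` lattice.

    Cells are identified by ``id_fn(r, c)`` (default ``"N{r}_{c}"``) and
    ordered row-major.  With ``torus=True`` edges wrap, giving every cell
    exactly four neighbors (useful for exactness checks).
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    if id_fn is None:
        id_fn = lambda r, c: f"N{r}_{c}"
    ids = [id_fn(r, c) for r in range(rows) for c in range(cols)]
    nbrs: dict = {i: set() for i in ids}
    for r in range(rows):
        for c in range(cols):
            here = id_fn(r, c)
            steps = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            for rr, cc in steps:
                if torus:
                    rr, cc = rr % rows, cc % cols
                elif not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                other = id_fn(rr, cc)
                if other != here:
                    nbrs[here].add(other)
    return SpatialWeights(ids=ids, neighbors=nbrs)


def polygon_rook_weights(
    geometries: Mapping[Hashable, "object"], min_shared_length: float = 1e-9
) -> SpatialWeights:
    """Rook contiguity from polygons: neighbors share a boundary segment
    of positive length; corner-only (point) contact is excluded."""
    ids = list(geometries)
    nbrs: dict = {i: set() for i in ids}
    for k, i in enumerate(ids):
        gi = geometries[i]
        for j in ids[k + 1 :]:
            inter = gi.boundary.intersection(geometries[j].boundary)
            if getattr(inter, "length", 0.0) > min_shared_length:
                nbrs[i].add(j)
                nbrs[j].add(i)
    return SpatialWeights(ids=ids, neighbors=nbrs)
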