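"""Shared analysis spaces and neighborhood queries.

Two concrete spaces are supported: a triangulated cortical surface mesh
(:class:`SurfaceMesh`) whose adjacency is the edge set of its faces, and a
3-D voxel grid (:class:`VolumeGrid`) with face-adjacency (6-connectivity).
Both expose the same minimal protocol — ``n_elements`` and ``neighbors(e)`` —
which is all the maximum-probability-map tie-breaking and cleanup rules need.
A generic :class:`AdjacencySpace` wraps an arbitrary undirected graph for
testing and for label data that arrives with a precomputed neighbor structure.

Neighborhoods are purely graph-topological: ``degree`` counts adjacency
steps, never millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError

__all__ = [
    "SurfaceMesh",
    "VolumeGrid",
    "AdjacencySpace",
    "build_adjacency",
    "neighbors_within_degree",
    "triangulated_grid_mesh",
]


def build_adjacency(n_vertices: int, faces: Sequence[Sequence[int]]) -> list[frozenset[int]]:
    """Derive per-vertex neighbor sets from a triangle face list.

    Adjacency is exactly the undirected edge set of the faces: two vertices
    are neighbors iff they share an edge of at least one triangle. The result
    is symmetric and irreflexive by construction.

    Raises
    ------
    GeometryError
        If any face index falls outside ``[0, n_vertices)`` or some vertex is
        referenced by no face.
    """
    adj: list[set[int]] = [set() for _ in range(n_vertices)]
    referenced = np.zeros(n_vertices, dtype=bool)
    for face in faces:
        a, b, c = (int(v) for v in face)
        for v in (a, b, c):
            if not 0 <= v < n_vertices:
                raise GeometryError(
                    f"face vertex {v} out of range [0, {n_vertices})"
                )
            referenced[v] = True
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    if not referenced.all():
        missing = int(np.flatnonzero(~referenced)[0])
        raise GeometryError(f"vertex {missing} is referenced by no face")
    return [frozenset(s) for s in adj]


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface with face-derived vertex adjacency.

    Parameters
    ----------
    n_vertices
        Number of vertices; all face indices must lie in ``[0, n_vertices)``.
    faces
        ``(m, 3)`` array of vertex-index triples.
    coordinates
        Optional ``(n_vertices, 3)`` vertex positions in mm, needed only for
        surface-area statistics.
    """

    n_vertices: int
    faces: np.ndarray
    coordinates: np.ndarray | None = None
    _adjacency: tuple[frozenset[int], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "faces", faces)
        object.__setattr__(
            self, "_adjacency", tuple(build_adjacency(self.n_vertices, faces))
        )
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (self.n_vertices, 3):
                raise GeometryError(
                    f"coordinates shape {coords.shape} != ({self.n_vertices}, 3)"
                )
            object.__setattr__(self, "coordinates", coords)

    @property
    def n_elements(self) -> int:
        return self.n_vertices

    def neighbors(self, element: int) -> frozenset[int]:
        _check_element(self, element)
        return self._adjacency[element]

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area share in mm²: one third of each incident triangle."""
        if self.coordinates is None:
            raise GeometryError("mesh has no coordinates; areas undefined")
        p = self.coordinates
        tri = p[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri_area = 0.5 * np.linalg.norm(cross, axis=1)
        areas = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(areas, self.faces[:, k], tri_area / 3.0)
        return areas


@dataclass(frozen=True)
class VolumeGrid:
    """3-D voxel grid with 6-connectivity (face-adjacent neighbors).

    Linear element indices are 0-based row-major over ``(i, j, k)``:
    ``index = (i * nj + j) * nk + k``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GeometryError(f"invalid grid shape {self.shape!r}")
        object.__setattr__(self, "shape", shape)

    @property
    def n_elements(self) -> int:
        ni, nj, nk = self.shape
        return ni * nj * nk

    def to_ijk(self, element: int) -> tuple[int, int, int]:
        _check_element(self, element)
        _, nj, nk = self.shape
        i, rem = divmod(element, nj * nk)
        j, k = divmod(rem, nk)
        return i, j, k

    def to_linear(self, ijk: Sequence[int]) -> int:
        i, j, k = (int(v) for v in ijk)
        ni, nj, nk = self.shape
        if not (0 <= i < ni and 0 <= j < nj and 0 <= k < nk):
            raise GeometryError(f"voxel {(i, j, k)} outside grid {self.shape}")
        return (i * nj + j) * nk + k

    def contains_ijk(self, ijk: Sequence[int]) -> bool:
        return all(0 <= int(v) < s for v, s in zip(ijk, self.shape))

    def neighbors(self, element: int) -> frozenset[int]:
        i, j, k = self.to_ijk(element)
        out = []
        for d in (-1, 1):
            for axis, (a, b, c) in enumerate(
                ((i + d, j, k), (i, j + d, k), (i, j, k + d))
            ):
                if self.contains_ijk((a, b, c)):
                    out.append(self.to_linear((a, b, c)))
        return frozenset(out)


@dataclass(frozen=True)
class AdjacencySpace:
    """Arbitrary undirected graph space (e.g. a path graph in tests)."""

    adjacency: tuple[frozenset[int], ...]

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "AdjacencySpace":
        adj: list[set[int]] = [set() for _ in range(n)]
        for u, v in edges:
            if not (0 <= u < n and 0 <= v < n) or u == v:
                raise GeometryError(f"invalid edge ({u}, {v}) for n={n}")
            adj[u].add(v)
            adj[v].add(u)
        return cls(tuple(frozenset(s) for s in adj))

    @property
    def n_elements(self) -> int:
        return len(self.adjacency)

    def neighbors(self, element: int) -> frozenset[int]:
        _check_element(self, element)
        return self.adjacency[element]


def _check_element(space, element: int) -> None:
    if not 0 <= int(element) < space.n_elements:
        raise GeometryError(
            f"element {element} out of range [0, {space.n_elements})"
        )


def neighbors_within_degree(space, element: int, degree: int) -> set[int]:
    """All elements reachable in at most ``degree`` adjacency steps.

    The seed element itself is excluded. For a :class:`VolumeGrid` with
    ``degree=1`` this is the 6-connected face-adjacent shell.
    """
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    _check_element(space, element)
    seen = {int(element)}
    frontier = [int(element)]
    out: set[int] = set()
    for _ in range(degree):
        nxt: list[int] = []
        for v in frontier:
            for u in space.neighbors(v):
                if u not in seen:
                    seen.add(u)
                    out.add(u)
                    nxt.append(u)
        if not nxt:
            break
        frontier = nxt
    return out


def triangulated_grid_mesh(
    n_rows: int, n_cols: int, spacing_mm: float = 1.0
) -> SurfaceMesh:
    """Regular planar triangulation of an ``n_rows x n_cols`` vertex lattice.

    Each lattice cell is split into two triangles. Handy as a synthetic
    stand-in for a cortical patch: every interior vertex has degree 6, like
    a typical recursively subdivided sphere mesh.
    """
    if n_rows < 2 or n_cols < 2:
        raise GeometryError("grid mesh needs at least 2x2 vertices")
    idx = lambda r, c: r * n_cols + c  # noqa: E731
    faces = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            a, b = idx(r, c), idx(r, c + 1)
            d, e = idx(r + 1, c), idx(r + 1, c + 1)
            faces.append((a, b, d))
            faces.append((b, e, d))
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack(
        [cc.ravel() * spacing_mm, rr.ravel() * spacing_mm, np.zeros(n_rows * n_cols)]
    )
    return SurfaceMesh(n_rows * n_cols, np.array(faces), coordinates=coords)
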