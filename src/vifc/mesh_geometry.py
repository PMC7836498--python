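"""Inter-vertex distances on a cortical mesh and within-radius queries.

The distance defining the "dominant cluster" of a vertex can be either
geodesic along the mesh or straight-line 3D Euclidean. Geodesic is the
default: it respects cortical topology (no shortcuts across sulci).
Geodesics are graph shortest paths (Dijkstra, edge weight = Euclidean
segment length) over the mesh edges augmented with one shortcut per pair
of adjacent triangles (joining the two vertices opposite the shared
edge). The augmentation cuts the metrication error of the plain edge
graph from ~15-20% worst case on a triangular lattice to a few percent
of the true surface geodesic, while staying ordinary Dijkstra.

Membership in a radius-``r`` ball is strict (``d < r``): a vertex at
exactly the threshold falls in the out-set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .surface_io import SurfaceMesh

__all__ = [
    "DistanceIndex",
    "geodesic_distances",
    "euclidean_distances",
    "build_distance_index",
    "edge_adjacency",
    "geodesic_graph",
]


def edge_adjacency(mesh: SurfaceMesh, *, weighted: bool = True) -> sparse.csr_matrix:
    """Symmetric sparse adjacency of the mesh edge graph.

    Weights are Euclidean edge lengths in mm when ``weighted``, else 1.
    """
    edges = mesh.edges()
    if weighted and edges.size:
        w = np.linalg.norm(
            mesh.vertex_coords[edges[:, 0]] - mesh.vertex_coords[edges[:, 1]], axis=1
        )
    else:
        w = np.ones(len(edges))
    n = mesh.n_vertices
    adj = sparse.coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    return (adj + adj.T).tocsr()


def across_face_shortcuts(mesh: SurfaceMesh) -> np.ndarray:
    """One shortcut pair per pair of face-adjacent triangles.

    For every interior mesh edge shared by two faces, the two vertices
    opposite that edge form a shortcut; adding these to the edge graph
    sharply reduces the lattice metrication error of graph geodesics.
    """
    if not mesh.n_faces:
        return np.empty((0, 2), dtype=np.int64)
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for u, v in ((a, b), (b, c), (a, c)):
            key = (min(int(u), int(v)), max(int(u), int(v)))
            edge_faces.setdefault(key, []).append(fi)
    pairs = []
    for (u, v), fl in edge_faces.items():
        if len(fl) == 2:
            opp = [int(w) for fi in fl for w in mesh.faces[fi] if w != u and w != v]
            if opp[0] != opp[1]:
                pairs.append((min(opp), max(opp)))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.array(pairs, dtype=np.int64), axis=0)


def geodesic_graph(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Weighted graph for geodesic distances: edges + across-face shortcuts.

    Where a shortcut pair coincides with an actual edge the smaller
    weight wins (they are equal anyway: both are the segment length).
    """
    pairs = np.vstack([mesh.edges(), across_face_shortcuts(mesh)])
    pairs = np.unique(pairs, axis=0)
    w = np.linalg.norm(
        mesh.vertex_coords[pairs[:, 0]] - mesh.vertex_coords[pairs[:, 1]], axis=1
    )
    n = mesh.n_vertices
    adj = sparse.coo_matrix((w, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    return (adj + adj.T).tocsr()


def _check_source(mesh: SurfaceMesh, source: int) -> None:
    if not 0 <= source < mesh.n_vertices:
        raise ValueError(f"source vertex {source} out of range [0, {mesh.n_vertices})")
    if not mesh.cortex_mask[source]:
        raise ValueError(f"source vertex {source} is masked out")


def geodesic_distances(
    mesh: SurfaceMesh, source: int, max_radius: float
) -> np.ndarray:
    """Edge-graph shortest-path distance from ``source`` to every vertex.

    Distances beyond ``max_radius`` are reported as ``inf``. Masked vertices
    are unreachable (``inf``) and may not serve as the source.
    """
    if max_radius <= 0:
        raise ValueError("max_radius must be > 0")
    _check_source(mesh, source)
    adj = _mask_adjacency(geodesic_graph(mesh), mesh.cortex_mask)
    dist = dijkstra(adj, directed=False, indices=source, limit=max_radius)
    dist[dist > max_radius] = np.inf
    return dist


def euclidean_distances(
    mesh: SurfaceMesh, source: int, max_radius: float
) -> np.ndarray:
    """Straight-line 3D distance from ``source``; ``inf`` beyond the radius."""
    if max_radius <= 0:
        raise ValueError("max_radius must be > 0")
    _check_source(mesh, source)
    dist = np.linalg.norm(mesh.vertex_coords - mesh.vertex_coords[source], axis=1)
    dist[dist > max_radius] = np.inf
    dist[~mesh.cortex_mask] = np.inf
    return dist


def _mask_adjacency(adj: sparse.csr_matrix, mask: np.ndarray) -> sparse.csr_matrix:
    if mask.all():
        return adj
    keep = sparse.diags(mask.astype(float))
    return (keep @ adj @ keep).tocsr()


@dataclass
class DistanceIndex:
    """Precomputed within-radius vertex sets for a fixed radius grid.

    For every unmasked vertex the index stores all unmasked vertices within
    ``max(radii)`` (self excluded) together with their distances;
    :meth:`within_radius` filters these to the strict ball ``d < r``.
    """

    mesh: SurfaceMesh
    radii: tuple[float, ...]
    metric: str
    neighbor_ids: list[np.ndarray] = field(repr=False)
    neighbor_dists: list[np.ndarray] = field(repr=False)

    @property
    def max_radius(self) -> float:
        return max(self.radii)

    def within_radius(self, vertex: int, radius: float) -> np.ndarray:
        """Unmasked vertices j != vertex with d(vertex, j) < radius."""
        if radius not in self.radii:
            raise KeyError(f"radius {radius} not in configured grid {self.radii}")
        ids = self.neighbor_ids[vertex]
        return ids[self.neighbor_dists[vertex] < radius]

    def distances_from(self, vertex: int) -> tuple[np.ndarray, np.ndarray]:
        """(neighbor ids, distances) within ``max_radius`` of ``vertex``."""
        return self.neighbor_ids[vertex], self.neighbor_dists[vertex]


def build_distance_index(
    mesh: SurfaceMesh, radii: Sequence[float], metric: str = "geodesic"
) -> DistanceIndex:
    """Precompute within-radius sets for every radius in ``radii``.

    ``radii`` must be sorted ascending and positive; ``metric`` is
    ``"geodesic"`` or ``"euclidean"``. Masked vertices get empty sets and
    never appear in any other vertex's set.
    """
    radii = tuple(float(r) for r in radii)
    if not radii:
        raise ValueError("radii must be non-empty")
    if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
        raise ValueError("radii must be positive and sorted ascending")
    if metric not in ("geodesic", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")

    n = mesh.n_vertices
    rmax = radii[-1]
    mask = mesh.cortex_mask
    neighbor_ids: list[np.ndarray] = []
    neighbor_dists: list[np.ndarray] = []

    if metric == "geodesic":
        adj = _mask_adjacency(geodesic_graph(mesh), mask)
        sources = np.flatnonzero(mask)
        dmat = dijkstra(adj, directed=False, indices=sources, limit=rmax)
        per_source = {int(s): dmat[k] for k, s in enumerate(sources)}
        for i in range(n):
            if not mask[i]:
                neighbor_ids.append(np.empty(0, dtype=np.int64))
                neighbor_dists.append(np.empty(0))
                continue
            d = per_source[i]
            sel = np.flatnonzero((d <= rmax) & mask & (np.arange(n) != i))
            neighbor_ids.append(sel.astype(np.int64))
            neighbor_dists.append(d[sel])
    else:
        coords = mesh.vertex_coords
        for i in range(n):
            if not mask[i]:
                neighbor_ids.append(np.empty(0, dtype=np.int64))
                neighbor_dists.append(np.empty(0))
                continue
            d = np.linalg.norm(coords - coords[i], axis=1)
            sel = np.flatnonzero((d <= rmax) & mask & (np.arange(n) != i))
            neighbor_ids.append(sel.astype(np.int64))
            neighbor_dists.append(d[sel])

    return DistanceIndex(
        mesh=mesh,
        radii=radii,
        metric=metric,
        neighbor_ids=neighbor_ids,
        neighbor_dists=neighbor_dists,
    )
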