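"""Geometric substrate: oriented point clouds, triangle meshes, edge-weighted
mesh graphs, graph geodesics, and the normal-covariance curvature field that
acts as the attraction force of the 3D active contour model.

All coordinates are millimetres end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .errors import EmptyMesh, Unreachable

logger = logging.getLogger(__name__)

_UNIT_TOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfacePointCloud:
    """Oriented points of the local wound region.

    positions : (n, 3) float64, mm
    normals   : (n, 3) float64, unit length
    colors    : optional (n, 3) float64 in [0, 1]
    """

    positions: np.ndarray
    normals: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.normals.shape != self.positions.shape:
            raise ValueError("normals must match positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        lengths = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(lengths - 1.0) > _UNIT_TOL):
            raise ValueError("normals must be unit length (within 1e-6)")
        if self.colors is not None:
            self.colors = np.ascontiguousarray(self.colors, dtype=np.float64)
            if self.colors.shape != self.positions.shape:
                raise ValueError("colors must be (n, 3)")

    @property
    def point_count(self) -> int:
        return self.positions.shape[0]


@dataclass
class TriangleSurfaceMesh:
    """Triangulated wound surface.

    vertices         : (v, 3) float64, mm
    triangles        : (f, 3) int64 vertex indices
    vertex_labels    : optional (v,) bool, True = wound
    vertex_normals   : optional (v, 3) unit vectors
    vertex_curvature : optional (v,) float64, >= 0
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_labels: Optional[np.ndarray] = None
    vertex_normals: Optional[np.ndarray] = None
    vertex_curvature: Optional[np.ndarray] = None
    # degenerate (zero-area) triangles are rejected by default; covers of
    # slit-like holes legitimately contain them (zero measure, watertight)
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (v, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (f, 3)")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle index out of range")
            if not self.allow_degenerate:
                areas = self.triangle_areas()
                if np.any(areas <= 1e-12):
                    raise ValueError("mesh contains a (near-)zero-area triangle")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=bool)
            if self.vertex_labels.shape != (len(self.vertices),):
                raise ValueError("vertex_labels must be (v,)")

    @property
    def vertex_count(self) -> int:
        return self.vertices.shape[0]

    @property
    def triangle_count(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def unique_edges(self) -> np.ndarray:
        """Unique undirected edges (e, 2), sorted low-high per row."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def computed_vertex_normals(self) -> np.ndarray:
        """Per-vertex normals, area-weighted over incident triangles.

        Uses stored normals when present; otherwise accumulates triangle
        cross products (whose magnitude is twice the area, giving the
        area weighting for free) and normalizes.
        """
        if self.vertex_normals is not None:
            return self.vertex_normals
        p = self.vertices[self.triangles]
        fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        lengths = np.linalg.norm(vn, axis=1)
        lengths[lengths == 0] = 1.0
        return vn / lengths[:, None]


@dataclass
class MeshGraph:
    """Edge-weighted graph of a triangle mesh: nodes are vertices, edges are
    triangle edges, weights are Euclidean edge lengths in mm."""

    n_nodes: int
    edges: np.ndarray      # (e, 2) int64, sorted per row
    weights: np.ndarray    # (e,) float64, strictly positive
    _csr: Optional[sparse.csr_matrix] = field(default=None, repr=False)
    _adjacency: Optional[list] = field(default=None, repr=False)

    @property
    def csr(self) -> sparse.csr_matrix:
        if self._csr is None:
            i, j = self.edges[:, 0], self.edges[:, 1]
            m = sparse.coo_matrix(
                (np.concatenate([self.weights, self.weights]),
                 (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(self.n_nodes, self.n_nodes),
            )
            self._csr = m.tocsr()
        return self._csr

    @property
    def adjacency(self) -> list:
        """adjacency[v] = int array of neighbors of v."""
        if self._adjacency is None:
            indptr, indices = self.csr.indptr, self.csr.indices
            self._adjacency = [indices[indptr[v]:indptr[v + 1]] for v in range(self.n_nodes)]
        return self._adjacency

    @property
    def mean_edge_length(self) -> float:
        return float(self.weights.mean())


@dataclass
class CameraView:
    """Pinhole camera: intrinsics in pixels, pose in mm.

    ``rotation`` maps camera coordinates to world coordinates (columns are
    the camera axes expressed in the world frame); ``center`` is the camera
    position; the third rotation column is the viewing axis pointing into
    the scene.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    rotation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must have determinant +1")

    @property
    def view_axis(self) -> np.ndarray:
        return self.rotation[:, 2]

    @property
    def pose_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.center
        return m


@dataclass
class CurvatureField:
    """Per-vertex attraction values: the largest eigenvalue of the covariance
    of surface normals gathered in a Euclidean ball around each vertex."""

    values: np.ndarray
    radius: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < -1e-15):
            raise ValueError("curvature values must be non-negative")
        self.values = np.maximum(self.values, 0.0)

    def normalized(self) -> np.ndarray:
        """Values rescaled to [0, 1] (max-to-one); zeros if the field is flat."""
        m = self.values.max() if self.values.size else 0.0
        if m <= 0:
            return np.zeros_like(self.values)
        return self.values / m


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_mesh_graph(mesh: TriangleSurfaceMesh) -> MeshGraph:
    """Weighted graph of a mesh: one node per vertex, one undirected edge per
    unique triangle edge, weight = Euclidean length."""
    if mesh.triangle_count == 0:
        raise EmptyMesh("mesh has no triangles")
    edges = mesh.unique_edges()
    weights = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    return MeshGraph(n_nodes=mesh.vertex_count, edges=edges, weights=weights)


def geodesic_distance(graph: MeshGraph, a: int, b: int) -> tuple[float, list[int]]:
    """Shortest-path length (mm) and vertex path from a to b on the graph."""
    if a == b:
        return 0.0, [a]
    dist, pred = csgraph.dijkstra(
        graph.csr, directed=False, indices=a, return_predecessors=True
    )
    if not np.isfinite(dist[b]):
        raise Unreachable(f"no path between {a} and {b}")
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return float(dist[b]), path


def geodesic_matrix(
    graph: MeshGraph,
    sources: Sequence[int],
    limit: float = np.inf,
    return_predecessors: bool = False,
):
    """Multi-source Dijkstra: distances (s, n) from each source to every node.

    ``limit`` truncates the search radius (entries beyond it are inf), which
    keeps the per-iteration contour updates cheap on large meshes.
    """
    return csgraph.dijkstra(
        graph.csr,
        directed=False,
        indices=np.asarray(sources, dtype=np.int64),
        limit=limit,
        return_predecessors=return_predecessors,
    )


def k_ring_neighborhood(graph: MeshGraph, v: int, k: int) -> set[int]:
    """All vertices reachable from v in at most k edges (v included)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    seen = {int(v)}
    frontier = [int(v)]
    adjacency = graph.adjacency
    for _ in range(k):
        nxt = []
        for u in frontier:
            for w in adjacency[u]:
                w = int(w)
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
        if not frontier:
            break
    return seen


def compute_curvature(
    mesh: TriangleSurfaceMesh,
    radius: float = 5.0,
    max_expected_neighbors: int = 600,
    chunk: int = 8192,
) -> CurvatureField:
    """Attraction field of the active contour: for each vertex, the largest
    eigenvalue of the (mean-centered) covariance of the unit normals of all
    vertices within Euclidean distance ``radius``.

    Flat regions give 0 (all normals identical); creases such as wound rims
    give large values, peaking where the ball holds a balanced mix of the
    two adjoining normal populations.

    On very dense meshes (e.g. after Midpoint subdivision) the neighbor pool
    is thinned by a deterministic stride so that a ball holds on the order
    of ``max_expected_neighbors`` pool points; the covariance is estimated
    from that uniform subsample. Meshes at scanner resolution are unaffected
    (no thinning when balls are small).

    Vertices with fewer than 3 in-radius neighbors get value 0 and are
    counted in a logged warning.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    normals = mesh.computed_vertex_normals()
    pts = mesh.vertices
    n = len(pts)

    # thin the neighbor pool if balls would be huge
    if n > max_expected_neighbors:
        bbox = pts.max(axis=0) - pts.min(axis=0)
        extent = np.prod(np.clip(bbox[bbox > 0], 1e-9, None)) if np.any(bbox > 0) else 1.0
        # crude surface-density estimate: points per unit area of bbox footprint
        dims = np.sort(bbox)[::-1]
        footprint = max(dims[0] * dims[1], 1e-9)
        density = n / footprint
        expected = density * np.pi * radius * radius
        stride = max(1, int(np.ceil(expected / max_expected_neighbors)))
    else:
        stride = 1
    pool_idx = np.arange(0, n, stride)
    tree = cKDTree(pts[pool_idx])
    pool_normals = normals[pool_idx]

    values = np.zeros(n)
    degenerate = 0
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        lists = tree.query_ball_point(pts[start:stop], radius)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=stop - start)
        ok = counts >= 3
        degenerate += int(np.sum(~ok))
        if not np.any(ok):
            continue
        flat = np.concatenate([lists[i] for i in np.nonzero(ok)[0]])
        nn = pool_normals[flat]
        bounds = np.concatenate([[0], np.cumsum(counts[ok])])
        seg = bounds[:-1]
        s1 = np.add.reduceat(nn, seg, axis=0)                      # sum n
        outer = nn[:, :, None] * nn[:, None, :]
        s2 = np.add.reduceat(outer.reshape(len(nn), 9), seg, axis=0)  # sum n n^T
        c = counts[ok].astype(np.float64)[:, None]
        mean = s1 / c
        cov = s2.reshape(-1, 3, 3) / c[:, :, None] - mean[:, :, None] * mean[:, None, :]
        eig = np.linalg.eigvalsh(cov)[:, -1]
        out = np.zeros(stop - start)
        out[ok] = np.maximum(eig, 0.0)
        values[start:stop] = out
    if degenerate:
        logger.warning(
            "compute_curvature: %d vertices had < 3 neighbors within %.3g mm "
            "(value set to 0)", degenerate, radius,
        )
    return CurvatureField(values=values, radius=radius)


def voxel_downsample(cloud: SurfacePointCloud, voxel_size: float) -> SurfacePointCloud:
    """Average positions, colors and normals per occupied voxel; mean normals
    are re-normalized to unit length."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    keys = np.floor(cloud.positions / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    k = counts.shape[0]

    def mean_by_voxel(arr: np.ndarray) -> np.ndarray:
        out = np.zeros((k, arr.shape[1]))
        np.add.at(out, inverse, arr)
        return out / counts[:, None]

    positions = mean_by_voxel(cloud.positions)
    normals = mean_by_voxel(cloud.normals)
    lengths = np.linalg.norm(normals, axis=1)
    lengths[lengths == 0] = 1.0
    normals = normals / lengths[:, None]
    colors = mean_by_voxel(cloud.colors) if cloud.colors is not None else None
    return SurfacePointCloud(positions=positions, normals=normals, colors=colors)
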