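"""From labeled points to a dense triangle mesh.

``triangulate_cloud`` performs a greedy projection-style triangulation of an
oriented point cloud: every point projects its radius neighborhood onto its
local tangent plane, triangulates it in 2D (Delaunay), and votes for the
triangles incident to itself; triangles confirmed by at least two of their
vertices are kept under an orientability guard (every undirected edge holds
at most two triangles, traversed in opposite directions). On evenly sampled
scanner-like clouds this reproduces the surface triangulation exactly (for
planar clouds, the global 2D Delaunay triangulation), while the
normal-deviation and radius limits prevent bridging across creases and gaps.

``midpoint_subdivide`` densifies the mesh without changing its geometry:
every edge is cut at its midpoint and each triangle is replaced by four
coplanar children. Densification gives the active contour more candidate
vertices per move.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .core_geometry import SurfacePointCloud, TriangleSurfaceMesh
from .errors import TriangulationFailed

logger = logging.getLogger(__name__)


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``normal``."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def triangulate_cloud(
    cloud: SurfacePointCloud,
    search_radius_factor: float = 3.0,
    max_neighbors: int = 100,
    max_surface_angle_deg: float = 60.0,
    labels: np.ndarray | None = None,
    min_votes: int = 2,
) -> TriangleSurfaceMesh:
    """Greedy local tangent-plane triangulation of an oriented cloud.

    Parameters mirror the usual greedy-projection knobs: neighborhoods reach
    ``search_radius_factor`` times the mean nearest-neighbor spacing, are
    capped at ``max_neighbors`` points, and exclude neighbors whose normals
    deviate from the seed normal by more than ``max_surface_angle_deg``.
    The angle limit must exceed the crease angle at the wound rim or the
    mesh cracks along it: a spherical-cap crater of aperture radius a and
    depth h meets the skin at asin(2ah / (a^2 + h^2)), 53 deg for the
    typical a = 2h, hence the 60 deg default.

    Per-point labels (wound / non-wound), when given, are carried onto the
    mesh vertices. Raises TriangulationFailed if more than 20% of the points
    end up in no triangle.
    """
    pts = cloud.positions
    normals = cloud.normals
    n = len(pts)
    if n < 3:
        raise TriangulationFailed("need at least 3 points")

    tree = cKDTree(pts)
    nn_d, _ = tree.query(pts, k=2)
    spacing = float(np.mean(nn_d[:, 1]))
    radius = search_radius_factor * spacing
    k = min(max_neighbors, n)
    dists, idx = tree.query(pts, k=k, distance_upper_bound=radius)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    cos_max = np.cos(np.radians(max_surface_angle_deg))

    votes: dict[tuple[int, int, int], int] = {}
    for i in range(n):
        valid = np.isfinite(dists[i])
        nbr = idx[i, valid]
        # drop neighbors across sharp creases relative to this point's normal
        nbr = nbr[normals[nbr] @ normals[i] >= cos_max]
        if len(nbr) < 3:
            continue
        # canonical input order so degenerate (cocircular) configurations
        # triangulate identically in every seed's neighborhood
        nbr = np.sort(nbr)
        t1, t2 = _tangent_basis(normals[i])
        rel = pts[nbr] - pts[i]
        uv = np.column_stack([rel @ t1, rel @ t2])
        try:
            dt = Delaunay(uv)
        except Exception:
            continue
        local_self = int(np.nonzero(nbr == i)[0][0]) if i in nbr else 0
        for tri in dt.simplices:
            if local_self not in tri:
                continue
            tri_global = tuple(sorted(int(nbr[t]) for t in tri))
            votes[tri_global] = votes.get(tri_global, 0) + 1

    # keep triangles confirmed by >= min_votes of their own vertices, best
    # first, under an orientability guard: every undirected edge may carry
    # at most two triangles, and they must traverse it in opposite
    # directions. This makes the surface consistently windable by
    # construction and rejects the rare crisscross overlaps that would
    # otherwise create slits and non-orientable micro-handles.
    candidates = sorted(
        (t for t, c in votes.items() if c >= min_votes),
        key=lambda t: (-votes[t], t),
    )
    used_directed: set[tuple[int, int]] = set()
    kept: list[tuple[int, int, int]] = []
    for t in candidates:
        # preferred winding: align with the member normals
        p0, p1, p2 = pts[t[0]], pts[t[1]], pts[t[2]]
        fn = np.cross(p1 - p0, p2 - p0)
        ref = normals[t[0]] + normals[t[1]] + normals[t[2]]
        tri = (t[0], t[1], t[2]) if fn @ ref >= 0 else (t[0], t[2], t[1])
        placed = False
        for cand in (tri, tri[::-1]):
            des = [(cand[0], cand[1]), (cand[1], cand[2]), (cand[2], cand[0])]
            if any(d in used_directed for d in des):
                continue
            used_directed.update(des)
            kept.append(cand)
            placed = True
            break
        if not placed:
            continue

    if not kept:
        raise TriangulationFailed("no triangles produced")
    triangles = np.array(kept, dtype=np.int64)

    used = np.zeros(n, dtype=bool)
    used[triangles.ravel()] = True
    isolated = int(np.sum(~used))
    if isolated > 0.2 * n:
        raise TriangulationFailed(
            f"{isolated} of {n} points isolated after triangulation"
        )
    if isolated:
        logger.info("triangulate_cloud: %d isolated points", isolated)

    # winding is consistent across shared edges by construction; align the
    # global orientation with the supplied normals
    p = pts[triangles]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    ref = normals[triangles].mean(axis=1)
    if float(np.einsum("ij,ij->i", fn, ref).sum()) < 0:
        triangles = np.ascontiguousarray(triangles[:, ::-1])

    vlabels = None
    if labels is not None:
        vlabels = np.asarray(labels, dtype=bool)
    return TriangleSurfaceMesh(
        vertices=pts.copy(),
        triangles=triangles,
        vertex_labels=vlabels,
        vertex_normals=normals.copy(),
    )


def midpoint_subdivide(mesh: TriangleSurfaceMesh, iterations: int = 2) -> TriangleSurfaceMesh:
    """Midpoint subdivision: each triangle becomes four coplanar children per
    iteration; new vertices are exact edge midpoints (created once per shared
    edge), original vertices are untouched, and the total area is preserved.

    Vertex labels propagate conservatively: a midpoint is wound only if both
    edge endpoints are wound. Vertex normals are averaged and re-normalized.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh
    for _ in range(iterations):
        out = _subdivide_once(out)
    return out


def _subdivide_once(mesh: TriangleSurfaceMesh) -> TriangleSurfaceMesh:
    v, f = mesh.vertices, mesh.triangles
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    unique, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (v[unique[:, 0]] + v[unique[:, 1]])
    mid_index = len(v) + np.arange(len(unique))
    m01, m12, m20 = (
        mid_index[inverse[: len(f)]],
        mid_index[inverse[len(f): 2 * len(f)]],
        mid_index[inverse[2 * len(f):]],
    )
    new_f = np.concatenate([
        np.column_stack([f[:, 0], m01, m20]),
        np.column_stack([f[:, 1], m12, m01]),
        np.column_stack([f[:, 2], m20, m12]),
        np.column_stack([m01, m12, m20]),
    ])
    new_v = np.concatenate([v, mid])

    labels = None
    if mesh.vertex_labels is not None:
        labels = np.concatenate([
            mesh.vertex_labels,
            mesh.vertex_labels[unique[:, 0]] & mesh.vertex_labels[unique[:, 1]],
        ])
    nrm = None
    if mesh.vertex_normals is not None:
        mid_n = mesh.vertex_normals[unique[:, 0]] + mesh.vertex_normals[unique[:, 1]]
        lengths = np.linalg.norm(mid_n, axis=1)
        lengths[lengths == 0] = 1.0
        nrm = np.concatenate([mesh.vertex_normals, mid_n / lengths[:, None]])
    return TriangleSurfaceMesh(
        vertices=new_v, triangles=new_f, vertex_labels=labels, vertex_normals=nrm
    )
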