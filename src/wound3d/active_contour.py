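"""3D active contour model (snake) on a triangle mesh.

The contour is a closed loop of mesh vertices initialized just outside the
wound (the fused masks are deliberately over-segmented) and attracted to the
wound rim by the surface curvature field, while an elastic term contracts it
and a smoothing term keeps it regular. The total energy over the n nodes is

    E_total   = E_mesh + E_contour
    E_mesh    = - sum_i M_i                      (normalized curvature)
    E_contour = alpha * E_elastic + beta * E_smooth
    E_elastic = sum_i geodesic(p_i, p_{i+1}) / L
    E_smooth  = sum_i ||p_{i+1} - 2 p_i + p_{i-1}||^2 / L^2

with cyclic indexing, geodesics taken along the mesh's edge-weighted graph,
and L the mean mesh edge length (the normalizations let alpha = beta = 1
balance a dimensionless eigenvalue against millimetre distances).

One iteration: (1) each node gathers its k-ring graph neighborhood
(2 hops by default); (2) each node greedily moves to the candidate that
minimizes its local energy, using its neighbors' pre-update positions;
(3) a periodic cubic spline is fit through the new positions; (4) the spline
is resampled uniformly in arc length at the same node count; (5) each sample
snaps back to the nearest mesh vertex. Node count is invariant throughout.

In the greedy step the elastic and smoothing contributions are expressed as
the node's share of the whole-contour energy, which makes the curvature
attraction the leading term of each move while the contour terms break ties
and the spline resampling enforces regularity; see docs/methods.md for why
a per-move-balanced weighting freezes the contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy.spatial import cKDTree

from .core_geometry import (
    CurvatureField,
    MeshGraph,
    TriangleSurfaceMesh,
    build_mesh_graph,
    compute_curvature,
    geodesic_matrix,
    k_ring_neighborhood,
)
from .errors import DegenerateContour, NoBoundary, OpenBoundary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """Ordered closed loop of mesh vertex indices (successor of the last node
    is the first)."""

    node_ids: np.ndarray
    mesh: TriangleSurfaceMesh = field(repr=False)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        if self.node_ids.ndim != 1 or len(self.node_ids) < 3:
            raise ValueError("contour needs at least 3 nodes")
        if self.node_ids.min() < 0 or self.node_ids.max() >= self.mesh.vertex_count:
            raise ValueError("contour node out of mesh range")

    @property
    def node_count(self) -> int:
        return len(self.node_ids)

    @property
    def positions(self) -> np.ndarray:
        return self.mesh.vertices[self.node_ids]


@dataclass
class ACMConfig:
    """Tunables of the active contour model.

    alpha, beta        : weights of the elastic and smoothing terms (1, 1)
    neighborhood_hops  : k-ring radius of per-node candidate sets (2)
    iterations         : number of snake iterations (10)
    curvature_radius   : mm ball for the normal-covariance curvature (5)
    """

    alpha: float = 1.0
    beta: float = 1.0
    neighborhood_hops: int = 2
    iterations: int = 10
    curvature_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha/beta must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.neighborhood_hops < 1:
            raise ValueError("neighborhood_hops must be >= 1")


@dataclass
class EnergyBreakdown:
    total: float
    mesh: float
    contour: float
    elastic: float
    smooth: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total, "mesh": self.mesh, "contour": self.contour,
            "elastic": self.elastic, "smooth": self.smooth,
        }


# ---------------------------------------------------------------------------
# initial contour
# ---------------------------------------------------------------------------

def _chain_boundary_loops(boundary_edges: np.ndarray) -> list[list[int]]:
    """Chain undirected boundary edges into closed vertex loops."""
    adjacency: dict[int, list[int]] = {}
    for a, b in boundary_edges:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted((int(a), int(b)))) for a, b in boundary_edges}
    loops: list[list[int]] = []
    while unused:
        start_edge = min(unused)
        unused.discard(start_edge)
        loop = [start_edge[0], start_edge[1]]
        while True:
            cur = loop[-1]
            nxt = None
            for cand in sorted(adjacency.get(cur, [])):
                e = tuple(sorted((cur, cand)))
                if e in unused:
                    nxt = cand
                    unused.discard(e)
                    break
            if nxt is None:
                break  # open chain: drop it
            if nxt == loop[0]:
                loops.append(loop)  # closed
                break
            loop.append(nxt)
    return loops


def extract_initial_contour(mesh: TriangleSurfaceMesh) -> Contour:
    """Initial wound contour from the labeled mesh.

    The wound submesh (triangles whose three vertices are all wound) is
    taken; its boundary edges (edges with exactly one incident wound
    triangle) are chained into closed loops; the longest loop is kept and
    every second node retained, halving the node count for the snake.
    """
    if mesh.vertex_labels is None:
        raise NoBoundary("mesh has no labels")
    labels = mesh.vertex_labels
    if not labels.any():
        raise NoBoundary("no wound vertices")
    if labels.all():
        raise NoBoundary("no non-wound vertices")
    wound_tris = mesh.triangles[labels[mesh.triangles].all(axis=1)]
    if len(wound_tris) == 0:
        raise NoBoundary("no fully wound-labeled triangle")
    e = np.concatenate([wound_tris[:, [0, 1]], wound_tris[:, [1, 2]], wound_tris[:, [2, 0]]])
    e.sort(axis=1)
    unique, counts = np.unique(e, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        raise NoBoundary("wound submesh has no boundary")
    loops = _chain_boundary_loops(boundary)
    if not loops:
        raise OpenBoundary(
            f"could not close a boundary loop; {len(boundary)} boundary edges, "
            f"first at vertices {tuple(boundary[0])}"
        )

    def loop_length(loop: list[int]) -> float:
        p = mesh.vertices[np.asarray(loop)]
        return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())

    loop = max(loops, key=loop_length)
    subsampled = np.asarray(loop[::2], dtype=np.int64)
    if len(subsampled) < 3:
        subsampled = np.asarray(loop, dtype=np.int64)
    return Contour(node_ids=subsampled, mesh=mesh)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def contour_energy(
    contour: Contour,
    graph: MeshGraph,
    curvature: CurvatureField,
    config: ACMConfig,
) -> EnergyBreakdown:
    """Energy of a contour state (normalized curvature attraction, geodesic
    elasticity, squared second-difference smoothness)."""
    ids = contour.node_ids
    pos = contour.positions
    mnorm = curvature.normalized()
    lbar = graph.mean_edge_length

    e_mesh = -float(mnorm[ids].sum())

    nxt = np.roll(ids, -1)
    dist = geodesic_matrix(graph, ids)
    seg = dist[np.arange(len(ids)), nxt]
    e_elastic = float(seg.sum()) / lbar

    second = np.roll(pos, -1, axis=0) - 2 * pos + np.roll(pos, 1, axis=0)
    e_smooth = float(np.sum(np.linalg.norm(second, axis=1) ** 2)) / lbar ** 2

    e_contour = config.alpha * e_elastic + config.beta * e_smooth
    return EnergyBreakdown(
        total=e_mesh + e_contour, mesh=e_mesh, contour=e_contour,
        elastic=e_elastic, smooth=e_smooth,
    )


# ---------------------------------------------------------------------------
# spline resampling and snapping
# ---------------------------------------------------------------------------

def fit_closed_spline(points: np.ndarray, n_samples: int, dense_factor: int = 25) -> np.ndarray:
    """Periodic cubic spline through ordered 3D points, resampled at
    ``n_samples`` positions uniformly spaced in arc length.

    The spline is parameterized by cumulative chord length. Consecutive
    duplicate points are merged before fitting; if fewer than 4 distinct
    points remain, a linear (polygonal) interpolant is used instead, and if
    the loop has (nearly) collapsed to a point DegenerateContour is raised.
    """
    points = np.asarray(points, dtype=np.float64)
    if n_samples < 4 or len(points) < 4:
        raise ValueError("need >= 4 points and n_samples >= 4")
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12
    pts = points[keep]
    if len(pts) > 1 and np.linalg.norm(pts[-1] - pts[0]) <= 1e-12:
        pts = pts[:-1]
    if len(pts) < 2 or np.max(np.linalg.norm(pts - pts[0], axis=1)) <= 1e-9:
        raise DegenerateContour("contour collapsed to a point")
    k = 3 if len(pts) >= 4 else 1
    closed = np.vstack([pts, pts[:1]])  # periodic fit expects explicit closure
    tck, _ = interpolate.splprep(closed.T, per=1, s=0, k=k)
    u_dense = np.linspace(0.0, 1.0, dense_factor * n_samples + 1)
    dense = np.asarray(interpolate.splev(u_dense, tck)).T
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, arc[-1], n_samples, endpoint=False)
    u_samples = np.interp(targets, arc, u_dense)
    return np.asarray(interpolate.splev(u_samples, tck)).T


def snap_to_mesh(points: np.ndarray, mesh: TriangleSurfaceMesh,
                 tree: cKDTree | None = None) -> np.ndarray:
    """Euclidean-nearest mesh vertex index for each query point (kd-tree);
    exact distance ties resolve to the lowest vertex index."""
    if mesh.vertex_count == 0:
        raise ValueError("empty mesh")
    if tree is None:
        tree = cKDTree(mesh.vertices)
    pts = np.atleast_2d(points)
    d, idx = tree.query(pts)
    idx = np.asarray(idx, dtype=np.int64)
    for i, (p, di) in enumerate(zip(pts, d)):
        ties = tree.query_ball_point(p, di + 1e-12)
        if len(ties) > 1:
            idx[i] = min(ties)
    return idx


# ---------------------------------------------------------------------------
# iteration and driver
# ---------------------------------------------------------------------------

def greedy_step(
    contour: Contour,
    graph: MeshGraph,
    curvature: CurvatureField,
    config: ACMConfig,
) -> np.ndarray:
    """Step 2 of the snake iteration: each node independently moves to the
    candidate in its k-ring minimizing its local energy (neighbors at their
    pre-update positions). Returns the new node ids; the current vertex wins
    exact ties, otherwise the lowest vertex index does. With alpha = beta =
    0 this reduces to a per-node argmax of curvature over the k-ring."""
    mesh = contour.mesh
    ids = contour.node_ids
    n = len(ids)
    mnorm = curvature.normalized()
    max_w = float(graph.weights.max())

    prev_ids = np.roll(ids, 1)
    next_ids = np.roll(ids, -1)
    pos = mesh.vertices

    # Normalize the contour terms as each node's share of the whole-contour
    # energy: the attraction term then leads the greedy move while elastic
    # and smoothing act as tie-breakers among near-equal-curvature
    # candidates; contour regularity is chiefly enforced by the spline
    # resampling of step 3. (With the contour terms at the same per-move
    # scale as the attraction, a unit-weight snake is too stiff to recover
    # the mask over-segmentation within the iteration budget.)
    seg_chord = np.linalg.norm(pos[ids] - pos[next_ids], axis=1)
    lbar_c = max(float(seg_chord.mean()), 1e-12)
    elastic_scale = n * lbar_c
    smooth_scale = n * lbar_c * lbar_c

    # distances from every current node to everything within reach of the
    # greedy moves; the limit keeps the search local, with an exact fallback
    limit = 3.0 * float(seg_chord.max()) + (config.neighborhood_hops + 2) * max_w
    unique_ids = np.unique(ids)
    dist = geodesic_matrix(graph, unique_ids, limit=limit)
    row_of = {int(v): r for r, v in enumerate(unique_ids)}

    new_ids = np.empty(n, dtype=np.int64)
    for i in range(n):
        cands = np.fromiter(
            k_ring_neighborhood(graph, int(ids[i]), config.neighborhood_hops),
            dtype=np.int64,
        )
        cands.sort()
        rp, rn = row_of[int(prev_ids[i])], row_of[int(next_ids[i])]
        g = dist[rp, cands] + dist[rn, cands]
        bad = ~np.isfinite(g)
        if bad.any():  # limit too tight here: recompute exactly for this node
            full = geodesic_matrix(graph, [int(prev_ids[i]), int(next_ids[i])])
            g = full[0, cands] + full[1, cands]
        second = pos[next_ids[i]] - 2 * pos[cands] + pos[prev_ids[i]]
        energy = (
            -mnorm[cands]
            + config.alpha * g / elastic_scale
            + config.beta * np.sum(second * second, axis=1) / smooth_scale
        )
        best = float(np.min(energy))
        cur_pos = int(np.nonzero(cands == ids[i])[0][0])
        if energy[cur_pos] <= best + 1e-12:
            new_ids[i] = ids[i]          # current vertex wins ties
        else:
            new_ids[i] = cands[int(np.argmin(energy))]  # lowest index on ties
    return new_ids


def acm_iteration(
    contour: Contour,
    graph: MeshGraph,
    curvature: CurvatureField,
    config: ACMConfig,
    tree: cKDTree | None = None,
) -> Contour:
    """One snake iteration: greedy per-node moves, periodic-spline fit,
    uniform arc-length resampling, nearest-vertex snap. Node count is
    preserved."""
    mesh = contour.mesh
    n = contour.node_count
    new_ids = greedy_step(contour, graph, curvature, config)
    try:
        resampled = fit_closed_spline(mesh.vertices[new_ids], n)
    except DegenerateContour:
        logger.warning("acm_iteration: contour degenerate, skipping resample")
        return Contour(node_ids=new_ids, mesh=mesh)
    snapped = snap_to_mesh(resampled, mesh, tree=tree)
    return Contour(node_ids=snapped, mesh=mesh)


def run_acm(
    initial: Contour,
    config: ACMConfig | None = None,
    graph: MeshGraph | None = None,
    curvature: CurvatureField | None = None,
) -> tuple[Contour, list[EnergyBreakdown]]:
    """Run the snake for ``config.iterations`` iterations, recording the
    energy breakdown after each. Graph and curvature are computed from the
    contour's mesh when not supplied."""
    config = config or ACMConfig()
    mesh = initial.mesh
    if graph is None:
        graph = build_mesh_graph(mesh)
    if curvature is None:
        curvature = (
            CurvatureField(values=mesh.vertex_curvature, radius=config.curvature_radius)
            if mesh.vertex_curvature is not None
            else compute_curvature(mesh, radius=config.curvature_radius)
        )
    tree = cKDTree(mesh.vertices)
    contour = initial
    trace: list[EnergyBreakdown] = []
    for it in range(config.iterations):
        contour = acm_iteration(contour, graph, curvature, config, tree=tree)
        e = contour_energy(contour, graph, curvature, config)
        trace.append(e)
        logger.info("ACM iteration %d: E_total=%.4f (mesh=%.4f contour=%.4f)",
                    it + 1, e.total, e.mesh, e.contour)
    return contour, trace
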