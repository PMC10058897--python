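"""Mesh graphs, geodesics, k-rings, curvature and voxel filtering."""

import numpy as np
import networkx as nx
import pytest

import wound3d as w
from wound3d.errors import EmptyMesh, Unreachable


def _nx_graph(graph: w.MeshGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for (a, b), wt in zip(graph.edges, graph.weights):
        g.add_edge(int(a), int(b), weight=float(wt))
    return g


class TestBuildMeshGraph:
    def test_right_triangle_weights(self, right_triangle_mesh):
        graph = w.build_mesh_graph(right_triangle_mesh)
        assert graph.n_nodes == 3
        assert sorted(np.round(graph.weights, 9)) == [3.0, 4.0, 5.0]

    def test_shared_edge_counted_once(self):
        vertices = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        mesh = w.TriangleSurfaceMesh(vertices=vertices,
                                     triangles=np.array([[0, 1, 2], [1, 3, 2]]))
        graph = w.build_mesh_graph(mesh)
        assert len(graph.weights) == 5

    def test_edge_set_matches_enumeration_oracle(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        oracle = set()
        for t in random_mesh_30.triangles:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                oracle.add((min(int(a), int(b)), max(int(a), int(b))))
        got = {(int(a), int(b)) for a, b in graph.edges}
        assert got == oracle

    def test_empty_mesh_rejected(self):
        mesh = w.TriangleSurfaceMesh(vertices=np.zeros((3, 3)),
                                     triangles=np.zeros((0, 3), dtype=int))
        with pytest.raises(EmptyMesh):
            w.build_mesh_graph(mesh)


class TestGeodesicDistance:
    def test_identity(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        assert w.geodesic_distance(graph, 4, 4) == (0.0, [4])

    def test_adjacent_pair_is_single_edge(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        a, b = graph.edges[0]
        length, path = w.geodesic_distance(graph, int(a), int(b))
        assert path == [int(a), int(b)]
        assert length == pytest.approx(float(graph.weights[0]))

    def test_all_pairs_match_networkx_oracle(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        oracle = dict(nx.all_pairs_dijkstra_path_length(_nx_graph(graph)))
        for a in range(graph.n_nodes):
            for b in range(a + 1, graph.n_nodes):
                length, path = w.geodesic_distance(graph, a, b)
                assert length == pytest.approx(oracle[a][b], abs=1e-9)
                assert path[0] == a and path[-1] == b

    def test_metric_properties(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        v = random_mesh_30.vertices
        rng = np.random.default_rng(0)
        for _ in range(40):
            a, b, c = rng.integers(0, graph.n_nodes, 3)
            dab, _ = w.geodesic_distance(graph, int(a), int(b))
            dba, _ = w.geodesic_distance(graph, int(b), int(a))
            dbc, _ = w.geodesic_distance(graph, int(b), int(c))
            dac, _ = w.geodesic_distance(graph, int(a), int(c))
            assert dab == pytest.approx(dba, abs=1e-9)
            assert dab >= np.linalg.norm(v[a] - v[b]) - 1e-9
            assert dac <= dab + dbc + 1e-9

    def test_unreachable(self, right_triangle_mesh):
        # two disconnected triangles
        vertices = np.vstack([right_triangle_mesh.vertices,
                              right_triangle_mesh.vertices + 100.0])
        mesh = w.TriangleSurfaceMesh(vertices=vertices,
                                     triangles=np.array([[0, 1, 2], [3, 4, 5]]))
        graph = w.build_mesh_graph(mesh)
        with pytest.raises(Unreachable):
            w.geodesic_distance(graph, 0, 4)


class TestKRing:
    def test_zero_ring_is_self(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        assert w.k_ring_neighborhood(graph, 7, 0) == {7}

    def test_triangle_one_ring(self, right_triangle_mesh):
        graph = w.build_mesh_graph(right_triangle_mesh)
        assert w.k_ring_neighborhood(graph, 0, 1) == {0, 1, 2}

    def test_matches_bfs_oracle(self, random_mesh_30):
        graph = w.build_mesh_graph(random_mesh_30)
        g = _nx_graph(graph)
        for v in range(0, graph.n_nodes, 3):
            for k in (1, 2, 3):
                oracle = set(nx.ego_graph(g, v, radius=k).nodes)
                assert w.k_ring_neighborhood(graph, v, k) == oracle


class TestCurvature:
    def test_planar_mesh_is_zero(self, labeled_grid_mesh):
        field = w.compute_curvature(labeled_grid_mesh, radius=3.0)
        assert np.all(field.values <= 1e-12)

    def test_explicit_normals_match_direct_eigendecomposition(self):
        # a triangle whose vertex normals are {(0,0,1),(0,0,1),(1,0,0)};
        # with a radius covering all vertices every value equals the largest
        # eigenvalue of the hand-assembled covariance of those normals
        normals = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        mesh = w.TriangleSurfaceMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            triangles=np.array([[0, 1, 2]]),
            vertex_normals=normals,
        )
        field = w.compute_curvature(mesh, radius=10.0)
        mean = normals.mean(axis=0)
        centered = normals - mean
        cov = centered.T @ centered / 3.0
        expected = float(np.linalg.eigvalsh(cov)[-1])
        assert np.allclose(field.values, expected, atol=1e-12)

    def test_rim_curvature_exceeds_flat(self):
        mesh, rim = w.make_hole_mesh(outer_radius=12, hole_radius=6, depth=4,
                                     spacing=1.0)
        field = w.compute_curvature(mesh, radius=3.0)
        flat = np.setdiff1d(np.arange(mesh.vertex_count), rim)
        assert field.values[rim].mean() > field.values[flat].mean()

    def test_rigid_invariance(self, random_mesh_30):
        field = w.compute_curvature(random_mesh_30, radius=2.0)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = w.TriangleSurfaceMesh(
            vertices=random_mesh_30.vertices @ rot.T + np.array([5.0, -2.0, 9.0]),
            triangles=random_mesh_30.triangles,
        )
        field2 = w.compute_curvature(moved, radius=2.0)
        assert np.allclose(field.values, field2.values, atol=1e-9)


class TestVoxelDownsample:
    def _cloud(self, positions):
        normals = np.tile([0.0, 0.0, 1.0], (len(positions), 1))
        return w.SurfacePointCloud(positions=np.asarray(positions, float),
                                   normals=normals)

    def test_single_voxel_collapses_to_centroid(self):
        cloud = self._cloud([[0.1, 0.1, 0.1], [0.2, 0.3, 0.2], [0.3, 0.2, 0.15]])
        out = w.voxel_downsample(cloud, 1.0)
        assert out.point_count == 1
        assert np.allclose(out.positions[0], cloud.positions.mean(axis=0))

    def test_grid_spaced_cloud_unchanged_in_count(self):
        pts = np.array([[i * 2.0, j * 2.0, 0.0] for i in range(4) for j in range(4)])
        out = w.voxel_downsample(self._cloud(pts), 1.0)
        assert out.point_count == 16

    def test_matches_hash_grouping_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-3, 3, (200, 3))
        cloud = self._cloud(pts)
        out = w.voxel_downsample(cloud, 0.8)
        groups: dict[tuple, list[int]] = {}
        for i, p in enumerate(pts):
            groups.setdefault(tuple(np.floor(p / 0.8).astype(int)), []).append(i)
        oracle = sorted(tuple(np.round(pts[idx].mean(axis=0), 9))
                        for idx in groups.values())
        got = sorted(tuple(q) for q in np.round(out.positions, 9))
        assert got == oracle


from hypothesis import given, settings, strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 16), voxel=st.floats(0.2, 3.0))
def test_voxel_downsample_conserves_mass(seed, voxel):
    """Voxel filtering preserves the point-mass centroid: the count-weighted
    mean of voxel means equals the mean of the input positions."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 120))
    pts = rng.uniform(-5, 5, (n, 3))
    cloud = w.SurfacePointCloud(positions=pts,
                                normals=np.tile([0.0, 0.0, 1.0], (n, 1)))
    out = w.voxel_downsample(cloud, voxel)
    keys = np.floor(pts / voxel).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
    assert out.point_count == len(counts)
    centroid = (out.positions * counts[:, None]).sum(axis=0) / n
    assert np.allclose(centroid, pts.mean(axis=0), atol=1e-9)
    lengths = np.linalg.norm(out.normals, axis=1)
    assert np.allclose(lengths, 1.0, atol=1e-9)


def test_subdivision_never_lengthens_shortest_paths(random_mesh_30):
    """More nodes on the same geometry can only shorten graph geodesics."""
    graph = w.build_mesh_graph(random_mesh_30)
    fine = w.midpoint_subdivide(random_mesh_30, 1)
    fine_graph = w.build_mesh_graph(fine)
    rng = np.random.default_rng(2)
    for _ in range(25):
        a, b = rng.integers(0, random_mesh_30.vertex_count, 2)
        coarse_len, _ = w.geodesic_distance(graph, int(a), int(b))
        fine_len, _ = w.geodesic_distance(fine_graph, int(a), int(b))
        assert fine_len <= coarse_len + 1e-9
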