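"""Shared fixtures: small analytic meshes and one full pipeline run on the
default synthetic wound (reused by the acceptance tests)."""

from __future__ import annotations

import numpy as np
import pytest

import wound3d as w


@pytest.fixture(scope="session")
def right_triangle_mesh():
    """One 3-4-5 right triangle."""
    vertices = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
    return w.TriangleSurfaceMesh(vertices=vertices, triangles=np.array([[0, 1, 2]]))


@pytest.fixture(scope="session")
def random_mesh_30():
    """A 30-vertex planar jittered-grid mesh for graph oracles."""
    rng = np.random.default_rng(11)
    ax = np.arange(6, dtype=float)
    gx, gy = np.meshgrid(ax, ax[:5])
    pts = np.column_stack([
        gx.ravel() + rng.uniform(-0.25, 0.25, 30),
        gy.ravel() + rng.uniform(-0.25, 0.25, 30),
        rng.uniform(-0.05, 0.05, 30),
    ])
    from scipy.spatial import Delaunay
    tri = Delaunay(pts[:, :2])
    return w.TriangleSurfaceMesh(vertices=pts, triangles=tri.simplices.astype(np.int64))


@pytest.fixture(scope="session")
def labeled_grid_mesh():
    """Regular planar grid mesh with a disk-shaped wound label."""
    ax = np.arange(-8.0, 8.5, 1.0)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    from scipy.spatial import Delaunay
    tri = Delaunay(pts[:, :2])
    labels = np.hypot(pts[:, 0], pts[:, 1]) <= 4.5
    return w.TriangleSurfaceMesh(
        vertices=pts, triangles=tri.simplices.astype(np.int64), vertex_labels=labels
    )


@pytest.fixture(scope="session")
def small_phantom():
    """Small crater phantom bundle (cheap; not the acceptance conditions)."""
    spec = w.PhantomSpec(
        aperture_radius=6.0, depth=3.0, sampling_spacing=1.0, n_views=3,
        mask_dilation_px=8, mask_jitter_px=1, image_size=256, focal_px=833.0,
        view_distance=200.0, base_half_extent=10.0, seed=3,
    )
    cloud, gt = w.generate_phantom(spec)
    recordings = w.render_views(cloud, gt, spec)
    return spec, cloud, gt, recordings


@pytest.fixture(scope="session")
def default_phantom_run():
    """Full pipeline on the default study conditions (a = 10 mm, h = 5 mm,
    0.5 mm sampling, 4 views, 30 px dilation, 2 px jitter); shared across
    the end-to-end acceptance tests."""
    spec = w.PhantomSpec(seed=7)
    cloud, gt = w.generate_phantom(spec)
    recordings = w.render_views(cloud, gt, spec)
    config = w.PipelineConfig(seed=7)
    result = w.segment(cloud, recordings, config)
    report, cut = w.measure(
        result,
        ground_truth=w.GroundTruth(
            perimeter=gt.perimeter, area=gt.aperture_area, volume=gt.cavity_volume
        ),
        config=config,
    )
    return {
        "spec": spec, "cloud": cloud, "gt": gt, "recordings": recordings,
        "config": config, "result": result, "report": report, "cut": cut,
    }
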