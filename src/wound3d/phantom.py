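"""Synthetic wound phantoms with analytic ground truth.

A phantom is a skin patch (plane or cylinder patch) with a spherical-cap
crater carved into it. The cap geometry gives closed forms against which
the whole pipeline is scored:

    rim perimeter   2 * pi * a
    aperture area   pi * a^2
    cavity volume   (pi * h / 6) * (3 a^2 + h^2)

for aperture radius a and depth h (h <= a). The generator also renders the
multi-view evidence the mask-fusion stage consumes — pinhole cameras on a
hemisphere above the crater, depth images by point-splat z-buffering, and
binary masks made from the true wound points, then dilated and
boundary-jittered to emulate the over-segmentation and calibration error of
a real 2D segmentation front end. All randomness flows from one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage.morphology import disk

from .core_geometry import CameraView, SurfacePointCloud, TriangleSurfaceMesh
from .mask_projection import (
    BinaryMask,
    DepthImage,
    Recording,
    RecordingSet,
    dilate_mask,
)

logger = logging.getLogger(__name__)


@dataclass
class Occluder:
    """Horizontal disc hovering over the scene that blocks specific views:
    its splats overwrite nearer depths in the listed views."""

    center: tuple[float, float, float]
    radius: float
    views: Optional[list[int]] = None  # None = all views


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic wound.

    Defaults are the conditions the pipeline is validated under: a 10 mm
    aperture, 5 mm deep crater sampled at 0.5 mm with 0.02 mm position
    noise, seen by 4 views whose masks are dilated by 30 px and boundary
    jittered by 2 px. Camera geometry (200 mm working distance, f = 2500 px,
    768 px images) puts one pixel at ~0.08 mm on the surface, so the 30 px
    dilation is ~2.4 mm of over-segmentation — the few-millimetre scale of
    the calibration error that dilation exists to absorb.
    """

    base: str = "plane"
    aperture_radius: float = 10.0        # a, mm
    depth: float = 5.0                   # h, mm
    sampling_spacing: float = 0.5        # mm
    noise_sigma: float = 0.02            # mm
    n_views: int = 4
    mask_dilation_px: int = 30
    mask_jitter_px: int = 2
    occluders: list[Occluder] = field(default_factory=list)
    seed: int = 0
    base_half_extent: Optional[float] = None  # mm; default a + 6
    cylinder_radius: float = 60.0        # mm, for base="cylinder-patch"
    # camera model
    view_distance: float = 200.0         # mm
    view_tilt_deg: float = 25.0          # from vertical
    image_size: int = 768                # px (square)
    focal_px: float = 2500.0

    def __post_init__(self) -> None:
        if self.aperture_radius <= 0:
            raise ValueError("aperture_radius must be > 0")
        if not (0 <= self.depth <= self.aperture_radius):
            raise ValueError("depth must satisfy 0 <= h <= a")
        if self.sampling_spacing <= 0:
            raise ValueError("sampling_spacing must be > 0")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.base not in ("plane", "cylinder-patch"):
            raise ValueError("base must be 'plane' or 'cylinder-patch'")

    @property
    def half_extent(self) -> float:
        return self.base_half_extent if self.base_half_extent is not None \
            else self.aperture_radius + 6.0


@dataclass
class PhantomGroundTruth:
    rim_polyline: np.ndarray          # (m, 3), dense true rim
    perimeter: float                  # 2 pi a
    aperture_area: float              # pi a^2
    cavity_volume: float              # (pi h / 6)(3 a^2 + h^2)
    wound_point_flags: np.ndarray     # (n,) bool, true labels


def _cap_surface(r: np.ndarray, a: float, h: float) -> tuple[np.ndarray, float, float]:
    """Depth z(r) <= 0 of the spherical cap at planar radius r, with the
    sphere radius R and center height c = R - h."""
    if h == 0:
        return np.zeros_like(r), np.inf, 0.0
    big_r = (a * a + h * h) / (2.0 * h)
    c = big_r - h
    z = c - np.sqrt(np.maximum(big_r * big_r - r * r, 0.0))
    return z, big_r, c


def generate_phantom(spec: PhantomSpec) -> tuple[SurfacePointCloud, PhantomGroundTruth]:
    """Sample the phantom surface on a jittered grid with analytic outward
    normals and Gaussian position noise; deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    ext, s = spec.half_extent, spec.sampling_spacing
    ax = np.arange(-ext, ext + s / 2, s)
    gx, gy = np.meshgrid(ax, ax)
    x = gx.ravel() + rng.uniform(-0.25 * s, 0.25 * s, gx.size)
    y = gy.ravel() + rng.uniform(-0.25 * s, 0.25 * s, gy.size)
    r = np.hypot(x, y)
    a, h = spec.aperture_radius, spec.depth

    inside = r < a
    z = np.zeros_like(x)
    normals = np.tile([0.0, 0.0, 1.0], (len(x), 1))
    if h > 0:
        z_cap, big_r, c = _cap_surface(r[inside], a, h)
        z[inside] = z_cap
        # outward normal points from the surface toward the sphere center
        p_in = np.column_stack([x[inside], y[inside], z[inside]])
        to_center = np.array([0.0, 0.0, c]) - p_in
        normals[inside] = to_center / np.linalg.norm(to_center, axis=1)[:, None]

    positions = np.column_stack([x, y, z])
    if spec.base == "cylinder-patch":
        # wrap the patch onto a cylinder of radius rho around the x axis:
        # y is arc length, the crater region stays locally intact
        rho = spec.cylinder_radius
        phi = y / rho
        wrapped = positions.copy()
        wrapped[:, 1] = (rho + z) * np.sin(phi)
        wrapped[:, 2] = (rho + z) * np.cos(phi) - rho
        n_wrapped = normals.copy()
        n_wrapped[:, 1] = normals[:, 1] * np.cos(phi) + normals[:, 2] * np.sin(phi)
        n_wrapped[:, 2] = -normals[:, 1] * np.sin(phi) + normals[:, 2] * np.cos(phi)
        positions, normals = wrapped, n_wrapped

    positions = positions + rng.normal(0.0, spec.noise_sigma, positions.shape)
    cloud = SurfacePointCloud(positions=positions, normals=normals)

    t = np.linspace(0.0, 2 * np.pi, 512, endpoint=False)
    rim = np.column_stack([a * np.cos(t), a * np.sin(t), np.zeros_like(t)])
    gt = PhantomGroundTruth(
        rim_polyline=rim,
        perimeter=2 * np.pi * a,
        aperture_area=np.pi * a * a,
        cavity_volume=(np.pi * h / 6.0) * (3 * a * a + h * h),
        wound_point_flags=inside,
    )
    return cloud, gt


# ---------------------------------------------------------------------------
# view rendering
# ---------------------------------------------------------------------------

def _camera_ring(spec: PhantomSpec) -> list[CameraView]:
    views = []
    tilt = np.radians(spec.view_tilt_deg)
    half = (spec.image_size - 1) / 2.0
    for k in range(spec.n_views):
        az = 2 * np.pi * k / spec.n_views
        center = spec.view_distance * np.array(
            [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)]
        )
        z_axis = -center / np.linalg.norm(center)       # look at the origin
        up = np.array([0.0, 0.0, 1.0])
        x_axis = np.cross(up, z_axis)
        if np.linalg.norm(x_axis) < 1e-9:
            x_axis = np.array([1.0, 0.0, 0.0])
        x_axis = x_axis / np.linalg.norm(x_axis)
        y_axis = np.cross(z_axis, x_axis)
        rotation = np.column_stack([x_axis, y_axis, z_axis])
        views.append(CameraView(
            fx=spec.focal_px, fy=spec.focal_px, cx=half, cy=half,
            width=spec.image_size, height=spec.image_size,
            rotation=rotation, center=center,
        ))
    return views


def _splat(view: CameraView, points: np.ndarray, depth: np.ndarray) -> None:
    """Z-buffer point splats (1 px footprint) into ``depth`` (0 = empty)."""
    p_cam = (points - view.center) @ view.rotation
    z = p_cam[:, 2]
    front = z > 0
    u = np.floor(view.fx * p_cam[front, 0] / z[front] + view.cx + 0.5).astype(np.int64)
    v = np.floor(view.fy * p_cam[front, 1] / z[front] + view.cy + 0.5).astype(np.int64)
    ok = (u >= 0) & (u < view.width) & (v >= 0) & (v < view.height)
    u, v, zz = u[ok], v[ok], z[front][ok]
    order = np.argsort(zz)[::-1]       # nearest written last wins
    depth[v[order], u[order]] = zz[order]


def _jitter_mask(mask: np.ndarray, jitter_px: int, rng: np.random.Generator) -> np.ndarray:
    """Corrupt the mask boundary: pixels within jitter_px of the boundary are
    flipped with probability 1/2 (emulates segmentation boundary noise)."""
    if jitter_px <= 0:
        return mask
    se = disk(jitter_px)
    band = ndimage.binary_dilation(mask, structure=se) ^ ndimage.binary_erosion(mask, structure=se)
    flip = band & (rng.random(mask.shape) < 0.5)
    return mask ^ flip


def render_views(
    cloud: SurfacePointCloud, gt: PhantomGroundTruth, spec: PhantomSpec
) -> RecordingSet:
    """Render the recording set: depth by point-splat z-buffering of the
    cloud (occluders overwrite nearer depths), masks by projecting the true
    wound points and applying dilation + boundary jitter."""
    rng = np.random.default_rng(spec.seed + 1)
    records = []
    for k, view in enumerate(_camera_ring(spec)):
        depth = np.zeros((view.height, view.width))
        _splat(view, cloud.positions, depth)
        for occ in spec.occluders:
            if occ.views is not None and k not in occ.views:
                continue
            step = spec.view_distance / spec.focal_px  # ~1 px on the surface
            ax = np.arange(-occ.radius, occ.radius + step / 2, step)
            ox, oy = np.meshgrid(ax, ax)
            keep = ox * ox + oy * oy <= occ.radius * occ.radius
            pts = np.column_stack([
                ox[keep] + occ.center[0], oy[keep] + occ.center[1],
                np.full(keep.sum(), occ.center[2]),
            ])
            occ_depth = np.zeros_like(depth)
            _splat(view, pts, occ_depth)
            closer = (occ_depth > 0) & ((depth == 0) | (occ_depth < depth))
            depth[closer] = occ_depth[closer]

        mask = np.zeros((view.height, view.width), dtype=bool)
        wound_depth = np.zeros_like(depth)
        _splat(view, cloud.positions[gt.wound_point_flags], wound_depth)
        mask[wound_depth > 0] = True
        if spec.mask_dilation_px > 0:
            mask = dilate_mask(BinaryMask(mask), spec.mask_dilation_px).grid
        mask = _jitter_mask(mask, spec.mask_jitter_px, rng)
        records.append(Recording(view=view, depth=DepthImage(depth), mask=BinaryMask(mask)))
    return RecordingSet(records=records)


# ---------------------------------------------------------------------------
# synthetic hole mesh (snake test case)
# ---------------------------------------------------------------------------

def make_hole_mesh(
    outer_radius: float = 20.0,
    hole_radius: float = 10.0,
    depth: float = 5.0,
    spacing: float = 0.5,
    label_margin: float = 3.0,
) -> tuple[TriangleSurfaceMesh, np.ndarray]:
    """Plate with a steep-walled cylindrical depression — the classic snake
    test surface. Returns the mesh (with wound labels covering the hole plus
    ``label_margin`` of over-segmentation, emulating a dilated mask) and the
    tagged rim vertex indices (the ring where the wall meets the plate).

    The wall is a near-vertical slope one and a half grid cells wide so the
    surface stays a height field over the plate.
    """
    if hole_radius >= outer_radius:
        raise ValueError("hole_radius must be < outer_radius")
    ax = np.arange(-outer_radius, outer_radius + spacing / 2, spacing)
    gx, gy = np.meshgrid(ax, ax)
    x, y = gx.ravel(), gy.ravel()
    r = np.hypot(x, y)
    keep = r <= outer_radius
    x, y, r = x[keep], y[keep], r[keep]
    wall = 1.5 * spacing
    z = np.where(
        r >= hole_radius, 0.0,
        np.where(r <= hole_radius - wall, -depth,
                 -depth * (hole_radius - r) / wall),
    )
    tri2d = Delaunay(np.column_stack([x, y]))
    mesh = TriangleSurfaceMesh(
        vertices=np.column_stack([x, y, z]),
        triangles=tri2d.simplices.astype(np.int64),
        vertex_labels=r <= hole_radius + label_margin,
    )
    # orient upward
    p = mesh.vertices[mesh.triangles]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = fn[:, 2] < 0
    mesh.triangles[flip] = mesh.triangles[flip][:, ::-1]
    rim = np.nonzero(np.abs(r - hole_radius) <= 0.5 * spacing)[0]
    return mesh, rim
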