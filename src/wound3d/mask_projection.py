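"""Fusing per-view 2D binary wound masks onto the 3D point cloud.

Each reconstructed point is reprojected into every recording. A view is
usable for a point when the point lands in frame, the surface faces the
camera, and the depth the sensor measured at that pixel agrees with the
depth the reprojection predicts (large disagreement means another surface
occludes the point in that view). Among usable views the one with the best
score — closer camera and more frontal surface — donates its mask value:

    score = 1 / ||P - C_p||  *  1 / max(theta_deg, 1 deg)

with theta_deg the angle between the surface normal and the reverse of the
camera viewing axis, in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core_geometry import CameraView, SurfacePointCloud
from .errors import DegenerateGeometry

logger = logging.getLogger(__name__)

THETA_MIN_DEG = 1.0          # clamp for a perfectly camera-facing normal
DEPTH_INVALID = 0.0          # sentinel in depth grids


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DepthImage:
    """Depth along the camera view axis, mm; 0 marks invalid pixels."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("depth grid must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("valid depths must be > 0 (0 = invalid)")


@dataclass
class BinaryMask:
    """Wound / non-wound pixels, registered to the owning view's depth grid."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")


@dataclass
class Recording:
    view: CameraView
    depth: DepthImage
    mask: BinaryMask

    def __post_init__(self) -> None:
        shape = (self.view.height, self.view.width)
        if self.depth.grid.shape != shape or self.mask.grid.shape != shape:
            raise ValueError("depth/mask dimensions must match the camera view")


@dataclass
class RecordingSet:
    records: list[Recording]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("RecordingSet needs at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ReprojectionSample:
    """One (point, view) reprojection: pixel, predicted depth d_o, sensor
    depth d_m at that pixel, their absolute difference, and the view score."""

    view_index: int
    pixel: tuple[float, float]
    observed_depth: float
    in_frame: bool
    measured_depth: Optional[float] = None
    score: Optional[float] = None

    @property
    def depth_difference(self) -> Optional[float]:
        if self.measured_depth is None:
            return None
        return abs(self.measured_depth - self.observed_depth)


@dataclass
class LabeledCloud:
    cloud: SurfacePointCloud
    labels: np.ndarray        # (n,) bool
    source_view: np.ndarray   # (n,) int, -1 = no usable view

    def __post_init__(self) -> None:
        n = self.cloud.point_count
        self.labels = np.asarray(self.labels, dtype=bool)
        self.source_view = np.asarray(self.source_view, dtype=np.int64)
        if self.labels.shape != (n,) or self.source_view.shape != (n,):
            raise ValueError("labels/source_view must have one entry per point")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dilate_mask(mask: BinaryMask, radius_px: int = 30) -> BinaryMask:
    """Morphological dilation with a disk structuring element.

    The over-segmentation this produces is intentional: it absorbs camera
    calibration error and 2D segmentation error, and the active contour
    later tightens the boundary back onto the actual wound rim.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return BinaryMask(mask.grid.copy())
    out = ndimage.binary_dilation(mask.grid, structure=disk(radius_px))
    return BinaryMask(out)


def project_point(view: CameraView, point: np.ndarray) -> ReprojectionSample:
    """Pinhole projection of one world point into a view (pixel + d_o)."""
    p_cam = view.rotation.T @ (np.asarray(point, dtype=np.float64) - view.center)
    z = p_cam[2]
    if z <= 0:
        return ReprojectionSample(view_index=-1, pixel=(np.nan, np.nan),
                                  observed_depth=float(z), in_frame=False)
    u = view.fx * p_cam[0] / z + view.cx
    v = view.fy * p_cam[1] / z + view.cy
    in_frame = (0 <= u < view.width) and (0 <= v < view.height)
    return ReprojectionSample(view_index=-1, pixel=(float(u), float(v)),
                              observed_depth=float(z), in_frame=in_frame)


def unproject_pixel(view: CameraView, u: float, v: float, depth: float) -> np.ndarray:
    """Inverse of project_point: pixel + depth along view axis -> world point."""
    p_cam = np.array([
        (u - view.cx) * depth / view.fx,
        (v - view.cy) * depth / view.fy,
        depth,
    ])
    return view.rotation @ p_cam + view.center


def reprojection_score(point: np.ndarray, normal: np.ndarray, view: CameraView) -> float:
    """Score of a view for a point: closer camera and more frontal surface
    are better. The normal/view-axis angle is clamped below at 1 degree to
    avoid the singularity of a perfectly frontal surface; back-facing
    surfaces (angle > 90 deg) are not scored — discard them upstream."""
    point = np.asarray(point, dtype=np.float64)
    dist = float(np.linalg.norm(point - view.center))
    if dist < 1e-9:
        raise DegenerateGeometry("point coincides with the camera center")
    cosang = float(np.clip(-np.dot(normal, view.view_axis), -1.0, 1.0))
    theta = math.degrees(math.acos(cosang))
    return (1.0 / dist) * (1.0 / max(theta, THETA_MIN_DEG))


def occlusion_test(sample: ReprojectionSample, depth_tolerance: float = 5.0) -> bool:
    """True when the sensor saw a surface closer than the reprojected point:
    the point is hidden in this view and the view's mask must not label it."""
    if not sample.in_frame:
        raise ValueError("occlusion test requires an in-frame sample")
    if sample.measured_depth is None:
        return False  # invalid depth: unusable, but not proven occluded
    return sample.measured_depth < sample.observed_depth - depth_tolerance


def sample_view(recording: Recording, view_index: int, point: np.ndarray,
                normal: np.ndarray) -> ReprojectionSample:
    """Full reprojection sample of one point in one recording (scalar path;
    assign_optimal_labels is the vectorized equivalent)."""
    s = project_point(recording.view, point)
    s.view_index = view_index
    if not s.in_frame:
        return s
    iu = int(math.floor(s.pixel[0] + 0.5))
    iv = int(math.floor(s.pixel[1] + 0.5))
    iu = min(max(iu, 0), recording.view.width - 1)
    iv = min(max(iv, 0), recording.view.height - 1)
    d_m = recording.depth.grid[iv, iu]
    s.measured_depth = float(d_m) if d_m != DEPTH_INVALID else None
    cosang = -np.dot(normal, recording.view.view_axis)
    if cosang > 0:  # front-facing only
        s.score = reprojection_score(point, normal, recording.view)
    return s


def assign_optimal_labels(
    cloud: SurfacePointCloud,
    recordings: RecordingSet,
    depth_tolerance: float = 5.0,
) -> LabeledCloud:
    """Per-point optimal mask fusion.

    For each point and view: discard out-of-frame, back-facing,
    invalid-depth and occluded samples (|d_m - d_o| > depth_tolerance);
    among survivors pick the view with maximal score (ties go to the lower
    view index) and take its mask value at the nearest pixel. Points with no
    surviving view are labeled non-wound with source_view -1.
    """
    n = cloud.point_count
    n_views = len(recordings)
    scores = np.full((n_views, n), -np.inf)
    mask_vals = np.zeros((n_views, n), dtype=bool)

    for k, rec in enumerate(recordings):
        view = rec.view
        p_cam = (cloud.positions - view.center) @ view.rotation
        z = p_cam[:, 2]
        front = z > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = view.fx * p_cam[:, 0] / z + view.cx
            v = view.fy * p_cam[:, 1] / z + view.cy
        iu = np.floor(u + 0.5).astype(np.int64)
        iv = np.floor(v + 0.5).astype(np.int64)
        in_frame = front & (u >= 0) & (u < view.width) & (v >= 0) & (v < view.height)
        iu = np.clip(iu, 0, view.width - 1)
        iv = np.clip(iv, 0, view.height - 1)

        d_m = rec.depth.grid[iv, iu]
        valid_depth = d_m != DEPTH_INVALID
        agree = np.abs(d_m - z) <= depth_tolerance

        cosang = np.clip(-(cloud.normals @ view.view_axis), -1.0, 1.0)
        frontal = cosang > 0.0
        usable = in_frame & valid_depth & agree & frontal
        if not np.any(usable):
            continue
        dist = np.linalg.norm(cloud.positions - view.center, axis=1)
        theta = np.degrees(np.arccos(cosang))
        s = (1.0 / np.maximum(dist, 1e-9)) * (1.0 / np.maximum(theta, THETA_MIN_DEG))
        scores[k, usable] = s[usable]
        mask_vals[k] = rec.mask.grid[iv, iu]

    best = np.argmax(scores, axis=0)          # first max -> lower view index on ties
    has_view = np.isfinite(scores[best, np.arange(n)])
    labels = np.where(has_view, mask_vals[best, np.arange(n)], False)
    source_view = np.where(has_view, best, -1)

    n_orphan = int(np.sum(~has_view))
    if n_orphan > n // 2:
        logger.warning(
            "assign_optimal_labels: %d of %d points have no usable view", n_orphan, n
        )
    return LabeledCloud(cloud=cloud, labels=labels, source_view=source_view)
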