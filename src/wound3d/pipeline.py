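"""End-to-end orchestration: label fusion -> triangulation -> subdivision ->
initial contour -> active contour -> cut -> fill -> measure."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .active_contour import (
    ACMConfig,
    Contour,
    EnergyBreakdown,
    extract_initial_contour,
    run_acm,
)
from .config import PipelineConfig
from .core_geometry import (
    MeshGraph,
    SurfacePointCloud,
    TriangleSurfaceMesh,
    build_mesh_graph,
    compute_curvature,
    voxel_downsample,
)
from .mask_projection import LabeledCloud, RecordingSet, assign_optimal_labels
from .measurement import (
    GroundTruth,
    MeasurementReport,
    WoundCut,
    cut_wound_mesh,
    measure_wound,
)
from .meshing import midpoint_subdivide, triangulate_cloud

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    labeled: LabeledCloud
    mesh: TriangleSurfaceMesh            # subdivided, labeled
    graph: MeshGraph
    initial_contour: Contour
    contour: Contour
    energy_trace: list[EnergyBreakdown] = field(default_factory=list)


def segment(
    cloud: SurfacePointCloud,
    recordings: RecordingSet,
    config: Optional[PipelineConfig] = None,
) -> SegmentationResult:
    """Run the segmentation stages on a reconstructed cloud plus recordings."""
    config = config or PipelineConfig()
    if config.voxel_size_mm:
        cloud = voxel_downsample(cloud, config.voxel_size_mm)
        logger.info("voxel downsample to %d points", cloud.point_count)

    labeled = assign_optimal_labels(cloud, recordings, config.depth_tolerance_mm)
    logger.info("labeled %d/%d points wound", int(labeled.labels.sum()),
                cloud.point_count)

    base_mesh = triangulate_cloud(
        cloud,
        search_radius_factor=config.gpt_search_radius_factor,
        max_neighbors=config.gpt_max_neighbors,
        max_surface_angle_deg=config.gpt_max_surface_angle_deg,
        labels=labeled.labels,
    )
    logger.info("triangulated: %d vertices, %d triangles",
                base_mesh.vertex_count, base_mesh.triangle_count)

    # the initial contour is extracted at acquisition resolution (sparser
    # nodes), then refined on the subdivided mesh: midpoint subdivision
    # keeps every original vertex at the same index
    initial_ids = extract_initial_contour(base_mesh).node_ids
    mesh = midpoint_subdivide(base_mesh, config.subdivision_iterations)
    logger.info("subdivided: %d vertices, %d triangles",
                mesh.vertex_count, mesh.triangle_count)

    graph = build_mesh_graph(mesh)
    curvature = compute_curvature(mesh, radius=config.curvature_radius_mm)
    mesh.vertex_curvature = curvature.values

    initial = Contour(node_ids=initial_ids, mesh=mesh)
    logger.info("initial contour: %d nodes", initial.node_count)
    acm_cfg = ACMConfig(
        alpha=config.alpha, beta=config.beta,
        neighborhood_hops=config.neighborhood_hops,
        iterations=config.acm_iterations,
        curvature_radius=config.curvature_radius_mm,
    )
    final, trace = run_acm(initial, acm_cfg, graph=graph, curvature=curvature)
    return SegmentationResult(
        labeled=labeled, mesh=mesh, graph=graph,
        initial_contour=initial, contour=final, energy_trace=trace,
    )


def measure(
    result: SegmentationResult,
    ground_truth: Optional[GroundTruth] = None,
    config: Optional[PipelineConfig] = None,
) -> tuple[MeasurementReport, WoundCut]:
    """Cut the wound enclosed by the final contour and measure it."""
    config = config or PipelineConfig()
    cut = cut_wound_mesh(result.mesh, result.contour, result.graph)
    report = measure_wound(
        cut, result.contour, result.graph,
        ground_truth=ground_truth,
        perimeter_mode=config.perimeter_mode,
        flat_threshold_mm=config.flat_threshold_mm,
    )
    return report, cut
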