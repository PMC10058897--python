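"""File formats of the pipeline.

Point clouds and meshes travel as PLY (ascii or binary little-endian, via
trimesh) with unit-declaring comments; per-vertex wound labels and curvature
ride along as extra PLY vertex properties. Masks are 8-bit PNGs (0 /
255), depth images 16-bit PNGs in 0.1 mm units with 0 = invalid, and a JSON
manifest lists per-recording file paths, intrinsics and the 4x4 row-major
camera pose in mm. Contours and measurement reports serialize to JSON (and
CSV for reports).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import trimesh
import trimesh.exchange.ply as _ply

from .active_contour import Contour, EnergyBreakdown
from .core_geometry import CameraView, SurfacePointCloud, TriangleSurfaceMesh
from .errors import InputValidationError
from .mask_projection import BinaryMask, DepthImage, Recording, RecordingSet
from .measurement import MeasurementReport

DEPTH_SCALE = 0.1  # one uint16 step = 0.1 mm


# ---------------------------------------------------------------------------
# PLY: clouds and meshes
# ---------------------------------------------------------------------------

def _ply_raw_vertex(path: Path) -> dict[str, np.ndarray]:
    """All per-vertex properties of a PLY file, by name."""
    with open(path, "rb") as fh:
        kwargs = _ply.load_ply(fh)
    raw = kwargs["metadata"]["_ply_raw"]["vertex"]["data"]
    if isinstance(raw, dict):
        return {k: np.asarray(v).ravel() for k, v in raw.items()}
    return {name: np.asarray(raw[name]) for name in raw.dtype.names}


def save_cloud(cloud: SurfacePointCloud, path: str | Path) -> None:
    path = Path(path)
    m = trimesh.Trimesh(
        vertices=cloud.positions,
        faces=np.zeros((0, 3), dtype=np.int64),
        vertex_normals=cloud.normals,
        process=False,
    )
    if cloud.colors is not None:
        m.visual.vertex_colors = (np.clip(cloud.colors, 0, 1) * 255).astype(np.uint8)
    data = _ply.export_ply(m, encoding="binary_little_endian", include_attributes=True)
    path.write_bytes(data)


def load_cloud(path: str | Path) -> SurfacePointCloud:
    props = _ply_raw_vertex(Path(path))
    try:
        positions = np.column_stack([props["x"], props["y"], props["z"]]).astype(np.float64)
        normals = np.column_stack([props["nx"], props["ny"], props["nz"]]).astype(np.float64)
    except KeyError as exc:
        raise InputValidationError(f"{path}: cloud PLY needs x/y/z and nx/ny/nz") from exc
    lengths = np.linalg.norm(normals, axis=1)
    lengths[lengths == 0] = 1.0
    normals = normals / lengths[:, None]
    colors = None
    if all(k in props for k in ("red", "green", "blue")):
        colors = np.column_stack(
            [props["red"], props["green"], props["blue"]]
        ).astype(np.float64) / 255.0
    return SurfacePointCloud(positions=positions, normals=normals, colors=colors)


def save_mesh(mesh: TriangleSurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    m = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    if mesh.vertex_labels is not None:
        m.vertex_attributes["label"] = mesh.vertex_labels.astype(np.uint8)
    if mesh.vertex_curvature is not None:
        m.vertex_attributes["curvature"] = mesh.vertex_curvature.astype(np.float32)
    data = _ply.export_ply(m, encoding="binary_little_endian", include_attributes=True)
    path.write_bytes(data)


def load_mesh(path: str | Path) -> TriangleSurfaceMesh:
    path = Path(path)
    tm = trimesh.load(path, process=False, force="mesh")
    props = _ply_raw_vertex(path) if path.suffix.lower() == ".ply" else {}
    labels = props.get("label")
    curvature = props.get("curvature")
    return TriangleSurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        triangles=np.asarray(tm.faces, dtype=np.int64),
        vertex_labels=labels.astype(bool) if labels is not None else None,
        vertex_curvature=curvature.astype(np.float64) if curvature is not None else None,
    )


# ---------------------------------------------------------------------------
# PNG: masks and depth
# ---------------------------------------------------------------------------

def save_mask(mask: BinaryMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> BinaryMask:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    return BinaryMask(img >= 128)


def save_depth(depth: DepthImage, path: str | Path) -> None:
    steps = np.round(depth.grid / DEPTH_SCALE)
    if np.any(steps > np.iinfo(np.uint16).max):
        raise ValueError("depth exceeds the 6553.5 mm range of the 16-bit dialect")
    iio.imwrite(Path(path), steps.astype(np.uint16))


def load_depth(path: str | Path) -> DepthImage:
    img = np.asarray(iio.imread(Path(path)))
    return DepthImage(img.astype(np.float64) * DEPTH_SCALE)


# ---------------------------------------------------------------------------
# recording manifest
# ---------------------------------------------------------------------------

def save_recordings(recordings: RecordingSet, out_dir: str | Path) -> Path:
    """Write depth/mask PNGs plus manifest.json into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, rec in enumerate(recordings):
        depth_name, mask_name = f"depth_{k:02d}.png", f"mask_{k:02d}.png"
        save_depth(rec.depth, out / depth_name)
        save_mask(rec.mask, out / mask_name)
        entries.append({
            "depth": depth_name,
            "mask": mask_name,
            "intrinsics": {
                "fx": rec.view.fx, "fy": rec.view.fy,
                "cx": rec.view.cx, "cy": rec.view.cy,
                "width": rec.view.width, "height": rec.view.height,
            },
            "pose_row_major": rec.view.pose_matrix.ravel().tolist(),
        })
    manifest = {
        "units": "mm",
        "depth_dialect": "uint16 PNG, 0.1 mm per step, 0 = invalid",
        "records": entries,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_recordings(manifest_path: str | Path) -> RecordingSet:
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputValidationError(f"cannot read manifest {manifest_path}: {exc}") from exc
    records = manifest.get("records", [])
    if not records:
        raise InputValidationError(f"{manifest_path}: manifest lists no records")
    base = manifest_path.parent
    out = []
    for i, entry in enumerate(records):
        try:
            intr = entry["intrinsics"]
            pose = np.asarray(entry["pose_row_major"], dtype=np.float64).reshape(4, 4)
            view = CameraView(
                fx=intr["fx"], fy=intr["fy"], cx=intr["cx"], cy=intr["cy"],
                width=int(intr["width"]), height=int(intr["height"]),
                rotation=pose[:3, :3], center=pose[:3, 3],
            )
            depth = load_depth(base / entry["depth"])
            mask = load_mask(base / entry["mask"])
            out.append(Recording(view=view, depth=depth, mask=mask))
        except (KeyError, ValueError, OSError) as exc:
            raise InputValidationError(
                f"{manifest_path}: record {i} invalid: {exc}"
            ) from exc
    return RecordingSet(records=out)


# ---------------------------------------------------------------------------
# contours and reports
# ---------------------------------------------------------------------------

def save_contour(
    contour: Contour,
    path: str | Path,
    energy_trace: Optional[list[EnergyBreakdown]] = None,
) -> None:
    doc = {
        "units": "mm",
        "node_ids": contour.node_ids.tolist(),
        "positions": contour.positions.tolist(),
        "energy_trace": [e.as_dict() for e in energy_trace] if energy_trace else [],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def contour_to_obj(contour: Contour, path: str | Path) -> None:
    """Closed polyline export for visualization."""
    lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in contour.positions]
    n = contour.node_count
    lines.append("l " + " ".join(str(i + 1) for i in range(n)) + " 1")
    Path(path).write_text("\n".join(lines) + "\n")


def save_report(report: MeasurementReport, path_json: str | Path,
                path_csv: str | Path | None = None, wound_id: str = "wound") -> None:
    d = report.as_dict()
    Path(path_json).write_text(json.dumps(d, indent=2))
    if path_csv is not None:
        cols = ["wound_id", "perimeter_mm", "area_mm2", "surface_area_mm2",
                "volume_mm3", "err_perimeter_pct", "err_area_pct", "err_volume_pct"]
        with open(path_csv, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerow({"wound_id": wound_id, **{k: d.get(k) for k in cols[1:]}})
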