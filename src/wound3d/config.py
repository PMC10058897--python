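"""Pipeline configuration with the reference parameter set as defaults:
30 px mask dilation, 5 mm occlusion depth tolerance, 2 Midpoint subdivision
iterations, 5 mm curvature radius, alpha = beta = 1, 2-hop neighborhoods,
10 snake iterations, chordal perimeter."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import InputValidationError


@dataclass
class PipelineConfig:
    dilation_radius_px: int = 30
    depth_tolerance_mm: float = 5.0
    voxel_size_mm: Optional[float] = None          # None = no downsampling
    gpt_search_radius_factor: float = 3.0
    gpt_max_neighbors: int = 100
    gpt_max_surface_angle_deg: float = 60.0
    subdivision_iterations: int = 2
    curvature_radius_mm: float = 5.0
    alpha: float = 1.0
    beta: float = 1.0
    neighborhood_hops: int = 2
    acm_iterations: int = 10
    perimeter_mode: str = "chord"
    flat_threshold_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perimeter_mode not in ("geodesic", "chord"):
            raise InputValidationError("perimeter_mode must be 'geodesic' or 'chord'")
        if self.acm_iterations < 0 or self.subdivision_iterations < 0:
            raise InputValidationError("iteration counts must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise InputValidationError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise InputValidationError(
                f"{path}: unknown config fields {sorted(unknown)}"
            )
        return cls(**doc)
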