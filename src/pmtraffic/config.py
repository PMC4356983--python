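"""Pipeline configuration: every analysis knob, with YAML round-trip.

All defaults that are reconstructions rather than prescribed values live
here so they can be overridden from a single structured text file.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    # acquisition / containers
    bit_depth: int = 12
    filename_template: str = "{well}_f{field:02d}_ch{channel}.tif"
    channel_map: dict[str, str] = field(
        default_factory=lambda: {"1": "nuclei", "2": "total", "3": "surface"}
    )
    #: minimum image fields acquired per replicate well before image-level QC
    min_fields_per_replicate: int = 4
    # illumination correction
    smoothing_scale: int = 50
    illumination_max_images: int = 100
    # segmentation
    nucleus_min_area: int = 40
    nucleus_max_area: int = 2000
    nucleus_peak_min_distance: int = 5
    cell_threshold_policy: str = "otsu"
    # cell-level QC
    expression_gate_k: float = 3.0
    max_saturated_fraction: float = 0.01
    cell_area_range: tuple[float, float] = (100.0, 10000.0)
    min_form_factor: float = 0.3
    # image-level QC
    min_cells_per_image: int = 10
    focus_mad_multiplier: float = 3.0
    max_residual_background: float = 25.0
    # plate-level QC
    plate_max_failure_fraction: float = 0.75
    # scoring
    sem_multiplier_k: float = 2.0
    aggregation: str = "mean"  # mean | median (of per-image medians)
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (8 <= self.bit_depth <= 16):
            raise ParameterError(f"bit_depth must be in [8, 16], got {self.bit_depth}")
        if self.min_fields_per_replicate < 1:
            raise ParameterError("min_fields_per_replicate must be >= 1")
        if self.aggregation not in ("mean", "median"):
            raise ParameterError(f"aggregation must be mean|median, got {self.aggregation!r}")
        if set(self.channel_map.values()) != {"nuclei", "total", "surface"}:
            raise ParameterError(
                "channel_map must cover exactly the roles nuclei/total/surface"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_area_range"] = list(self.cell_area_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "cell_area_range" in d:
            d["cell_area_range"] = tuple(d["cell_area_range"])
        return cls(**d)

    def content_hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
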