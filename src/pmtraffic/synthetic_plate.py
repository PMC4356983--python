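"""Synthetic screening-plate generator with per-cell ground truth.

Produces multiwell plates of three-channel fields (nuclei stain, total
reporter, surface label) with the statistical structure the traffic assay
assumes: lognormal per-cell expression, a condition-specific true
surface/total ratio, smooth additive illumination gradients plus constant
background, detector saturation at the configured bit depth, apoptotic-like
small cells, defocused fields, and control wells for plate-level QC.

The noise and geometry parameters are free modelling choices of this
simulator (documented on :class:`SimulationConfig`), not measured values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi

from .core import CHANNEL_ROLES, NUCLEI, SURFACE, TOTAL, FieldImage
from .errors import ConfigurationError, ParameterError

CONTROL_ROLES = ("none", "negative", "positive", "transfection_control")


@dataclass
class IlluminationSpec:
    """Smooth additive illumination gradient for one channel.

    ``kind`` is ``"plane"`` (linear ramp along the image diagonal) or
    ``"radial"`` (center-bright dome). ``amplitude`` is the peak-to-baseline
    modulation as a fraction of the background level, in [0, 1).
    """

    kind: str = "radial"
    amplitude: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "radial"):
            raise ParameterError(f"illumination kind must be plane|radial, got {self.kind!r}")
        if not (0 <= self.amplitude < 1) or not np.isfinite(self.amplitude):
            raise ParameterError(f"illumination amplitude must be in [0, 1), got {self.amplitude}")

    def baseline(self, shape: tuple[int, int], background_level: float) -> np.ndarray:
        """Pixel-wise additive baseline: background scaled by the gradient."""
        rows, cols = shape
        rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
        if self.kind == "plane":
            pattern = (rr / max(rows - 1, 1) + cc / max(cols - 1, 1)) / 2.0
        else:
            r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
            d2 = ((rr - r0) / rows) ** 2 + ((cc - c0) / cols) ** 2
            pattern = 1.0 - d2 / 0.5  # 1 at center, 0 at the corners
            pattern = np.clip(pattern, 0.0, 1.0)
        return background_level * (1.0 + self.amplitude * pattern)


@dataclass
class ConditionSpec:
    """One treatment's simulation parameters.

    ``expression_mean``/``expression_sd`` parameterize the lognormal
    distribution of per-cell integrated total-reporter intensity on the
    linear (counts) scale.
    """

    name: str
    true_traffic_efficiency: float = 0.5
    n_cells_mean: float = 40.0
    expression_mean: float = 30000.0
    expression_sd: float = 12000.0
    frac_apoptotic: float = 0.0
    frac_saturating: float = 0.0
    frac_defocused_fields: float = 0.0
    control_role: str = "none"

    def __post_init__(self) -> None:
        for attr in (
            "true_traffic_efficiency",
            "n_cells_mean",
            "expression_mean",
            "expression_sd",
            "frac_apoptotic",
            "frac_saturating",
            "frac_defocused_fields",
        ):
            value = getattr(self, attr)
            if not np.isfinite(value):
                raise ParameterError(f"{self.name}: {attr} must be finite, got {value}")
        for attr in ("frac_apoptotic", "frac_saturating", "frac_defocused_fields"):
            value = getattr(self, attr)
            if not (0 <= value <= 1):
                raise ParameterError(f"{self.name}: {attr} must be in [0, 1], got {value}")
        if self.true_traffic_efficiency < 0:
            raise ParameterError(
                f"{self.name}: true_traffic_efficiency must be >= 0, "
                f"got {self.true_traffic_efficiency}"
            )
        if self.n_cells_mean < 0 or self.expression_mean <= 0 or self.expression_sd < 0:
            raise ParameterError(f"{self.name}: cell count and expression parameters invalid")
        if self.control_role not in CONTROL_ROLES:
            raise ParameterError(
                f"{self.name}: control_role must be one of {CONTROL_ROLES}, "
                f"got {self.control_role!r}"
            )


@dataclass
class SimulationConfig:
    """Plate-level simulation parameters.

    Geometry/noise defaults are modelling choices: cells are circular
    bodies (radius ~N(cell_radius_mean, cell_radius_sd), clipped) with a
    2-pixel perimeter band acting as the plasma membrane; apoptotic cells
    are rendered at half radius (<30% of normal area) with brighter
    condensed nuclei; defocus is a Gaussian blur of sigma
    ``defocus_sigma`` >= 4 applied to all channels of a field.
    """

    image_shape: tuple[int, int] = (256, 256)
    bit_depth: int = 12
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    conditions: list[ConditionSpec] = dc_field(default_factory=list)
    fields_per_well: int = 4
    replicate_wells_per_condition: int = 3
    illumination: dict[str, IlluminationSpec] = dc_field(
        default_factory=lambda: {
            NUCLEI: IlluminationSpec("plane", 0.25),
            TOTAL: IlluminationSpec("radial", 0.25),
            SURFACE: IlluminationSpec("radial", 0.25),
        }
    )
    background_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0
    # simulator-only knobs (free choices, documented above)
    cell_radius_mean: float = 8.0
    cell_radius_sd: float = 1.0
    membrane_band_px: float = 2.0
    nucleus_radius: float = 5.0
    nucleus_amplitude: float = 1200.0
    apoptotic_radius_factor: float = 0.5
    apoptotic_nucleus_radius: float = 4.0
    apoptotic_nucleus_brightness: float = 2.0
    defocus_sigma: float = 5.0
    transfection_phenotype_rate: float = 0.95

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ParameterError(f"image_shape must be positive, got {self.image_shape}")
        if not (8 <= self.bit_depth <= 16):
            raise ParameterError(f"bit_depth must be in [8, 16], got {self.bit_depth}")
        if self.fields_per_well < 1:
            raise ParameterError(f"fields_per_well must be >= 1, got {self.fields_per_well}")
        if self.replicate_wells_per_condition < 1:
            raise ParameterError("replicate_wells_per_condition must be >= 1")
        for value in (self.background_level, self.noise_sd):
            if not np.isfinite(value) or value < 0:
                raise ParameterError("background_level and noise_sd must be finite and >= 0")
        if self.defocus_sigma < 4:
            raise ParameterError("defocus_sigma must be >= 4 px to degrade sharpness metrics")

    @property
    def saturation_ceiling(self) -> int:
        return 2**self.bit_depth - 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_config_to_dict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return _config_from_dict(yaml.safe_load(Path(path).read_text()))


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["image_shape"] = list(config.image_shape)
    d["channel_roles"] = list(config.channel_roles)
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["image_shape"] = tuple(d.get("image_shape", (256, 256)))
    d["channel_roles"] = tuple(d.get("channel_roles", CHANNEL_ROLES))
    d["conditions"] = [ConditionSpec(**c) for c in d.get("conditions", [])]
    d["illumination"] = {
        role: IlluminationSpec(**spec) for role, spec in d.get("illumination", {}).items()
    }
    return SimulationConfig(**d)


@dataclass
class GroundTruth:
    """Per-cell, per-field and per-condition ground-truth tables."""

    cells: pd.DataFrame
    fields: pd.DataFrame
    conditions: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "ground_truth_cells.csv", index=False)
        self.fields.to_csv(outdir / "ground_truth_fields.csv", index=False)
        self.conditions.to_csv(outdir / "ground_truth_conditions.csv", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        return cls(
            cells=pd.read_csv(outdir / "ground_truth_cells.csv", keep_default_na=False),
            fields=pd.read_csv(outdir / "ground_truth_fields.csv", keep_default_na=False),
            conditions=pd.read_csv(outdir / "ground_truth_conditions.csv", keep_default_na=False),
        )


CELL_COLUMNS = [
    "condition",
    "well",
    "field",
    "cell",
    "row",
    "col",
    "radius",
    "true_total",
    "true_surface",
    "apoptotic",
    "saturated",
]
FIELD_COLUMNS = ["condition", "well", "field", "defocused", "phenotype"]


def _place_centroids(
    n: int, shape: tuple[int, int], margin: float, min_distance: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample up to ``n`` centroids with pairwise separation."""
    rows, cols = shape
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * max(n, 1)
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_distance**2 for pr, pc in placed):
            placed.append((r, c))
    return np.asarray(placed, dtype=float).reshape(-1, 2)


def _lognormal_counts(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws parameterized by linear-scale mean and sd."""
    if sd == 0:
        return np.full(size, mean)
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _add_disk(raster: np.ndarray, r0: float, c0: float, radius: float, value: float) -> int:
    """Add ``value`` to every pixel within ``radius`` of (r0, c0); returns pixel count."""
    mask = _disk_mask(raster.shape, r0, c0, radius)
    raster[mask] += value
    return int(mask.sum())


def _disk_mask(shape: tuple[int, int], r0: float, c0: float, radius: float) -> np.ndarray:
    rows, cols = shape
    rlo, rhi = max(int(r0 - radius) - 1, 0), min(int(r0 + radius) + 2, rows)
    clo, chi = max(int(c0 - radius) - 1, 0), min(int(c0 + radius) + 2, cols)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    mask[rlo:rhi, clo:chi] = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return mask


def simulate_field(
    spec: ConditionSpec,
    config: SimulationConfig,
    rng: np.random.Generator | int,
    well: str = "A01",
    field: int = 1,
) -> tuple[FieldImage, pd.DataFrame, pd.Series]:
    """Render one field and its ground-truth rows.

    Returns the three-channel :class:`FieldImage`, a per-cell ground-truth
    table and a per-field ground-truth row. Determinism: a fresh
    ``np.random.default_rng(seed)`` with identical inputs yields
    bit-identical images.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    shape = config.image_shape
    ceiling = config.saturation_ceiling

    n_cells = int(round(spec.n_cells_mean))
    min_distance = 2 * (config.cell_radius_mean + 2 * config.cell_radius_sd) + 3
    margin = config.cell_radius_mean + 3 * config.cell_radius_sd + 2
    centroids = _place_centroids(n_cells, shape, margin, min_distance, rng)
    n_cells = len(centroids)

    apoptotic = rng.random(n_cells) < spec.frac_apoptotic
    saturating = rng.random(n_cells) < spec.frac_saturating
    radii = np.clip(
        rng.normal(config.cell_radius_mean, config.cell_radius_sd, n_cells),
        config.cell_radius_mean - 2 * config.cell_radius_sd,
        config.cell_radius_mean + 2 * config.cell_radius_sd,
    )
    radii = np.where(apoptotic, radii * config.apoptotic_radius_factor, radii)
    totals = _lognormal_counts(spec.expression_mean, spec.expression_sd, n_cells, rng)
    surfaces = spec.true_traffic_efficiency * totals  # exact by construction

    signal = {role: np.zeros(shape, dtype=float) for role in config.channel_roles}
    rows = []
    for i in range(n_cells):
        r0, c0 = centroids[i]
        radius = radii[i]
        body = _disk_mask(shape, r0, c0, radius)
        n_body = int(body.sum())
        if n_body == 0:
            continue
        signal[TOTAL][body] += totals[i] / n_body
        band = body & ~_disk_mask(shape, r0, c0, max(radius - config.membrane_band_px, 0.5))
        n_band = int(band.sum())
        if n_band == 0:  # degenerate tiny cell: whole body is membrane
            band, n_band = body, n_body
        signal[SURFACE][band] += surfaces[i] / n_band
        nuc_radius = config.apoptotic_nucleus_radius if apoptotic[i] else config.nucleus_radius
        nuc_amp = config.nucleus_amplitude * (
            config.apoptotic_nucleus_brightness if apoptotic[i] else 1.0
        )
        _add_disk(signal[NUCLEI], r0, c0, nuc_radius, nuc_amp)
        rows.append(
            {
                "condition": spec.name,
                "well": well,
                "field": field,
                "cell": i + 1,
                "row": r0,
                "col": c0,
                "radius": radius,
                "true_total": totals[i],
                "true_surface": surfaces[i],
                "apoptotic": bool(apoptotic[i]),
                "saturated": bool(saturating[i]),
            }
        )

    defocused = bool(rng.random() < spec.frac_defocused_fields)
    phenotype = bool(
        spec.control_role == "transfection_control"
        and rng.random() < config.transfection_phenotype_rate
    )

    channels: dict[str, np.ndarray] = {}
    for role in config.channel_roles:
        scene = signal[role] + config.illumination[role].baseline(shape, config.background_level)
        if defocused:
            scene = ndi.gaussian_filter(scene, sigma=config.defocus_sigma)
        if config.noise_sd > 0:
            scene = scene + rng.normal(0.0, config.noise_sd, shape)
        channels[role] = scene

    # saturation is a detector effect: force the ceiling after optics/noise
    for i in range(n_cells):
        if saturating[i]:
            r0, c0 = int(round(centroids[i][0])), int(round(centroids[i][1]))
            channels[TOTAL][r0 : r0 + 2, c0 : c0 + 2] = ceiling + 1

    for role in config.channel_roles:
        channels[role] = np.clip(np.rint(channels[role]), 0, ceiling).astype(np.uint16)

    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    field_row = pd.Series(
        {
            "condition": spec.name,
            "well": well,
            "field": field,
            "defocused": defocused,
            "phenotype": phenotype,
        }
    )
    image = FieldImage(well=well, field=field, channels=channels, bit_depth=config.bit_depth)
    return image, cells, field_row


def well_name(index: int, plate_cols: int = 24) -> str:
    """Map a 0-based well index to a row-letter/column-number id (A01..P24...)."""
    row, col = divmod(index, plate_cols)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_plate(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[list[FieldImage], GroundTruth, pd.DataFrame]:
    """Simulate a full plate: conditions x replicate wells x fields.

    Returns the field images, the ground truth, and the plate layout table.
    When ``outdir`` is given, also writes per-channel 16-bit TIFFs (named by
    the default filename schema), ground-truth CSVs, the layout CSV, the
    per-image phenotype flags for transfection-control wells, and the
    configuration as YAML.
    """
    if not config.conditions:
        raise ConfigurationError("no conditions configured")
    if not any(c.control_role == "negative" for c in config.conditions):
        raise ConfigurationError("layout must include at least one negative control condition")

    seed_seq = np.random.SeedSequence(config.seed)
    images: list[FieldImage] = []
    cell_tables: list[pd.DataFrame] = []
    field_rows: list[pd.Series] = []
    layout_rows = []
    well_index = 0
    for spec in config.conditions:
        for _ in range(config.replicate_wells_per_condition):
            well = well_name(well_index)
            well_index += 1
            layout_rows.append(
                {
                    "well": well,
                    "condition": spec.name,
                    "class": "control" if spec.control_role != "none" else "siRNA",
                    "control_role": spec.control_role,
                }
            )
            for field in range(1, config.fields_per_well + 1):
                child = np.random.default_rng(seed_seq.spawn(1)[0])
                image, cells, field_row = simulate_field(
                    spec, config, child, well=well, field=field
                )
                images.append(image)
                cell_tables.append(cells)
                field_rows.append(field_row)

    cells = (
        pd.concat(cell_tables, ignore_index=True)
        if cell_tables
        else pd.DataFrame(columns=CELL_COLUMNS)
    )
    fields = pd.DataFrame(field_rows, columns=FIELD_COLUMNS)
    conditions = pd.DataFrame(
        {
            "condition": [c.name for c in config.conditions],
            "true_traffic_efficiency": [c.true_traffic_efficiency for c in config.conditions],
            "control_role": [c.control_role for c in config.conditions],
        }
    )
    truth = GroundTruth(cells=cells, fields=fields, conditions=conditions)
    layout = pd.DataFrame(layout_rows)

    if outdir is not None:
        _write_plate(config, images, truth, layout, Path(outdir))
    return images, truth, layout


def _write_plate(
    config: SimulationConfig,
    images: list[FieldImage],
    truth: GroundTruth,
    layout: pd.DataFrame,
    outdir: Path,
) -> None:
    from .pipeline_io import FilenameSchema  # local import to avoid a cycle

    outdir.mkdir(parents=True, exist_ok=True)
    schema = FilenameSchema()
    for image in images:
        for role, raster in image.channels.items():
            name = schema.format(image.well, image.field, role)
            tifffile.imwrite(outdir / name, raster)
    truth.write(outdir)
    layout.to_csv(outdir / "layout.csv", index=False)
    control_conditions = {
        c.name for c in config.conditions if c.control_role == "transfection_control"
    }
    flags = truth.fields[truth.fields["condition"].isin(control_conditions)]
    flags[["well", "field", "phenotype"]].to_csv(outdir / "phenotype_flags.csv", index=False)
    config.to_yaml(outdir / "simulation_config.yaml")
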