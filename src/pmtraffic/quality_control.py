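"""Three-level quality control: cells, images, and plate-level transfection.

Cell level: flag cells that do not significantly express the reporter,
have abnormal morphology (apoptotic-like), or contain a significant amount
of saturated pixels. Records are annotated, never deleted.

Image level: exclude out-of-focus fields (variance-of-Laplacian focus
score below a plate-adaptive gate), fields with high residual background
after correction, and fields with too few passing cells.

Plate level: a plate is accepted only if the expected transfection
phenotype is observed in enough control images; failure in more than 75%
of control images rejects the plate (strictly more than — a failure
fraction of exactly 0.75 is still accepted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import GateUndefinedError, ParameterError
from .segmentation import CellRecord

LOW_EXPRESSION = "low_expression"
SATURATED = "saturated"
ABNORMAL_MORPHOLOGY = "abnormal_morphology"

#: Plate rejection boundary: reject iff failure_fraction > this value.
PLATE_MAX_FAILURE_FRACTION = 0.75


@dataclass
class CellQCThresholds:
    """Gates for cell-level exclusion.

    None of these values is prescribed by the assay description; the
    defaults are reconstructions, exposed in the pipeline config.
    ``min_total_expression`` is in counts per pixel (mean over the mask);
    in the full pipeline it is derived per image as
    ``expression_gate_k`` x the robust sd of the cell-free residual
    background.
    """

    min_total_expression: float = 10.0
    max_saturated_fraction: float = 0.01
    area_range: tuple[float, float] = (100.0, 10000.0)
    min_form_factor: float = 0.3

    def __post_init__(self) -> None:
        low, high = self.area_range
        if low > high:
            raise ParameterError(f"area_range must be ordered, got {self.area_range}")
        if not (0 <= self.max_saturated_fraction <= 1):
            raise ParameterError("max_saturated_fraction must be in [0, 1]")


@dataclass
class ImageQCResult:
    well: str
    field: int
    focus_score: float
    residual_background: float
    n_cells_pass: int
    status: str  # pass | out_of_focus | high_background | too_few_cells


@dataclass
class PlateQCResult:
    plate_id: str
    n_control_images: int
    n_phenotype_positive: int
    failure_fraction: float
    accepted: bool


def flag_cells(
    cells: Iterable[CellRecord], thresholds: CellQCThresholds
) -> list[CellRecord]:
    """Annotate each cell with zero or more QC flags; never deletes records."""
    annotated = []
    for cell in cells:
        if cell.mean_total < thresholds.min_total_expression:
            cell.qc_flags.add(LOW_EXPRESSION)
        if any(
            count / cell.area > thresholds.max_saturated_fraction
            for count in cell.saturated_pixel_count.values()
        ):
            cell.qc_flags.add(SATURATED)
        low, high = thresholds.area_range
        if not (low <= cell.area <= high) or cell.form_factor < thresholds.min_form_factor:
            cell.qc_flags.add(ABNORMAL_MORPHOLOGY)
        annotated.append(cell)
    return annotated


def focus_score(nuclei_raster: np.ndarray) -> float:
    """Normalized variance of the Laplacian response; decreases under blur."""
    img = np.asarray(nuclei_raster, dtype=float)
    mean = img.mean()
    if mean <= 0:
        return 0.0
    return float(ndi.laplace(img).var() / mean**2)


def adaptive_focus_gate(scores: Sequence[float], mad_multiplier: float = 3.0) -> float:
    """Plate-adaptive focus gate: median - mad_multiplier x MAD across the plate."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise GateUndefinedError(
            "fewer than 4 images on the plate; the adaptive focus gate is undefined — "
            "supply a fixed focus gate instead"
        )
    median = np.median(scores)
    mad = np.median(np.abs(scores - median))
    return float(median - mad_multiplier * mad)


def assess_image(
    well: str,
    field: int,
    focus_score: float,
    residual_background: float,
    n_cells_pass: int,
    focus_gate: float,
    background_gate: float,
    min_cells: int = 10,
) -> ImageQCResult:
    """Classify one field's QC status; gate order: focus, background, cell count."""
    if focus_score < focus_gate:
        status = "out_of_focus"
    elif residual_background > background_gate:
        status = "high_background"
    elif n_cells_pass < min_cells:
        status = "too_few_cells"
    else:
        status = "pass"
    return ImageQCResult(
        well=well,
        field=field,
        focus_score=focus_score,
        residual_background=residual_background,
        n_cells_pass=n_cells_pass,
        status=status,
    )


def assess_plate_transfection(
    control_flags: Sequence[bool],
    plate_id: str = "",
    max_failure_fraction: float = PLATE_MAX_FAILURE_FRACTION,
) -> PlateQCResult:
    """Accept or reject a plate from per-control-image phenotype flags.

    ``control_flags[i]`` is True when the expected transfection phenotype
    was observed in control image *i*. Rejection requires the failure
    fraction to be *strictly* greater than ``max_failure_fraction``.
    """
    flags = list(control_flags)
    if not flags:
        raise ParameterError("assess_plate_transfection requires at least one control image flag")
    n_positive = int(sum(bool(f) for f in flags))
    failure_fraction = 1.0 - n_positive / len(flags)
    return PlateQCResult(
        plate_id=plate_id,
        n_control_images=len(flags),
        n_phenotype_positive=n_positive,
        failure_fraction=failure_fraction,
        accepted=failure_fraction <= max_failure_fraction,
    )


def expression_gate_from_background(robust_sd: float, k: float = 3.0) -> float:
    """Derive the per-image low-expression gate from measured background noise."""
    return k * robust_sd
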