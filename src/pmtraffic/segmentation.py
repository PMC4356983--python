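"""Nucleus and cell-body segmentation plus per-cell fluorescence integration.

Nuclei are detected on the corrected DNA-stain channel by Otsu
thresholding, hole filling and a distance-transform watershed to split
touching objects. Cell bodies grow from the nucleus seeds over the
corrected total-reporter channel, bounded by an automatic threshold, so
every retained nucleus yields exactly one disjoint cell with the same
label. Integrated intensities are plain sums over the cell mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .core import CHANNEL_ROLES, NUCLEI, SURFACE, TOTAL
from .errors import ShapeMismatchError

DEFAULT_MIN_NUCLEUS_AREA = 40
DEFAULT_MAX_NUCLEUS_AREA = 2000


@dataclass
class LabelMap:
    """Integer label raster (0 = background), labels contiguous from 1."""

    raster: np.ndarray
    provenance: str  # "nuclei" or "cells"

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)

    @property
    def n_labels(self) -> int:
        return int(self.raster.max())

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_labels + 1)


@dataclass
class CellRecord:
    """One segmented cell's integrated intensities, morphology and QC flags.

    Coordinates are 0-based, row-major. ``form_factor`` is 4*pi*A/P^2
    (1 for a circle; capped at 1.05 to absorb perimeter-estimate error on
    small objects). ``saturated_pixel_count`` is measured on the original,
    pre-correction rasters against the 2**bit_depth - 1 ceiling.
    """

    well: str
    field: int
    cell: int
    nucleus_row: float
    nucleus_col: float
    area: int
    form_factor: float
    nucleus_area: int
    integrated_total: float
    integrated_surface: float
    integrated_nuclei: float
    mean_total: float
    saturated_pixel_count: dict[str, int] = dc_field(default_factory=dict)
    qc_flags: set[str] = dc_field(default_factory=set)

    @property
    def passes_qc(self) -> bool:
        return not self.qc_flags


def _empty(provenance: str, shape: tuple[int, int]) -> LabelMap:
    return LabelMap(raster=np.zeros(shape, dtype=np.int32), provenance=provenance)


def segment_nuclei(
    nuclei_corrected: np.ndarray,
    min_area: int = DEFAULT_MIN_NUCLEUS_AREA,
    max_area: int = DEFAULT_MAX_NUCLEUS_AREA,
    peak_min_distance: int = 5,
) -> LabelMap:
    """Segment nuclei on the corrected DNA-stain channel.

    Otsu threshold -> fill holes -> watershed on the distance transform to
    split touching nuclei -> discard components outside [min_area, max_area].
    A blank image yields an empty map, not an error.
    """
    img = np.asarray(nuclei_corrected, dtype=float)
    if img.max() <= 0:
        return _empty("nuclei", img.shape)
    threshold = threshold_otsu(img)
    foreground = img > threshold
    if not foreground.any() or foreground.all():
        return _empty("nuclei", img.shape)
    foreground = ndi.binary_fill_holes(foreground)

    distance = ndi.distance_transform_edt(foreground)
    peaks = peak_local_max(
        distance, min_distance=peak_min_distance, labels=foreground, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(ndi.grey_dilation(markers, size=3) > 0)
    labels = watershed(-distance, markers=markers, mask=foreground)

    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, labels.max() + 1))
    keep = np.flatnonzero((areas >= min_area) & (areas <= max_area)) + 1
    filtered = np.where(np.isin(labels, keep), labels, 0)
    relabeled, _, _ = relabel_sequential(filtered)
    return LabelMap(raster=relabeled.astype(np.int32), provenance="nuclei")


def segment_cells(
    total_corrected: np.ndarray,
    nuclei: LabelMap,
    cell_threshold_policy: str | float = "otsu",
) -> LabelMap:
    """Grow cell bodies from nucleus seeds over the total-reporter channel.

    The growth region is bounded by ``cell_threshold_policy``: ``"otsu"``
    for an automatic threshold on the corrected channel, or a numeric
    threshold in counts. Cell labels equal their seed nucleus labels; a
    zero total channel degenerates each cell to its nucleus footprint.
    """
    img = np.asarray(total_corrected, dtype=float)
    if img.shape != nuclei.raster.shape:
        raise ShapeMismatchError("total channel and nuclei label map shapes differ")
    if nuclei.n_labels == 0:
        return _empty("cells", img.shape)
    if cell_threshold_policy == "otsu":
        threshold = threshold_otsu(img) if img.max() > 0 else np.inf
    else:
        threshold = float(cell_threshold_policy)
    mask = (img > threshold) | (nuclei.raster > 0)
    labels = watershed(-img, markers=nuclei.raster, mask=mask)
    return LabelMap(raster=labels.astype(np.int32), provenance="cells")


def measure_cells(
    cells: LabelMap,
    nuclei: LabelMap,
    corrected: dict[str, np.ndarray],
    original: dict[str, np.ndarray],
    bit_depth: int = 12,
    well: str = "",
    field: int = 0,
) -> list[CellRecord]:
    """Integrate fluorescence per cell and measure morphology.

    ``corrected`` holds the background-subtracted channels used for the
    intensity integrals; ``original`` holds the raw rasters used only for
    saturated-pixel counting at the 2**bit_depth - 1 ceiling.
    """
    if cells.raster.shape != nuclei.raster.shape:
        raise ShapeMismatchError("cell and nucleus label maps have different shapes")
    for role in CHANNEL_ROLES:
        if corrected[role].shape != cells.raster.shape:
            raise ShapeMismatchError(f"corrected {role} channel shape mismatch")
    n = cells.n_labels
    if n == 0:
        return []
    cell_labels = set(np.unique(cells.raster)) - {0}
    nucleus_labels = set(np.unique(nuclei.raster)) - {0}
    if not cell_labels <= nucleus_labels:
        raise ShapeMismatchError(
            f"cell labels without a matching nucleus label: {sorted(cell_labels - nucleus_labels)}"
        )
    index = np.arange(1, n + 1)
    ceiling = 2**bit_depth - 1

    sums = {
        role: ndi.sum_labels(np.asarray(corrected[role], dtype=float), cells.raster, index=index)
        for role in CHANNEL_ROLES
    }
    areas = ndi.sum_labels(np.ones_like(cells.raster), cells.raster, index=index).astype(int)
    nucleus_areas = ndi.sum_labels(
        np.ones_like(nuclei.raster), nuclei.raster, index=index
    ).astype(int)
    saturated = {
        role: ndi.sum_labels(
            (np.asarray(original[role]) >= ceiling).astype(float), cells.raster, index=index
        ).astype(int)
        for role in CHANNEL_ROLES
    }
    centroids = ndi.center_of_mass(np.ones_like(nuclei.raster), nuclei.raster, index=index)
    perimeters = {p.label: p.perimeter for p in regionprops(cells.raster)}

    records = []
    for i, label in enumerate(index):
        area = int(areas[i])
        if area == 0:  # label with no pixels cannot occur after relabeling
            continue
        perimeter = max(perimeters.get(label, 0.0), 1.0)
        form_factor = min(4.0 * np.pi * area / perimeter**2, 1.05)
        records.append(
            CellRecord(
                well=well,
                field=field,
                cell=int(label),
                nucleus_row=float(centroids[i][0]),
                nucleus_col=float(centroids[i][1]),
                area=area,
                form_factor=float(form_factor),
                nucleus_area=int(nucleus_areas[i]),
                integrated_total=float(sums[TOTAL][i]),
                integrated_surface=float(sums[SURFACE][i]),
                integrated_nuclei=float(sums[NUCLEI][i]),
                mean_total=float(sums[TOTAL][i] / area),
                saturated_pixel_count={role: int(saturated[role][i]) for role in CHANNEL_ROLES},
            )
        )
    return records
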