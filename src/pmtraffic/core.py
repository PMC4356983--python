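"""Shared domain types: channel roles and the per-field image container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError

#: Channel roles, in acquisition order: DNA stain, total reporter, surface label.
NUCLEI = "nuclei"
TOTAL = "total"
SURFACE = "surface"
CHANNEL_ROLES: tuple[str, str, str] = (NUCLEI, TOTAL, SURFACE)


@dataclass
class FieldImage:
    """One imaged field: a multichannel raster with well/field identity.

    Channels are stored per role as 2-D arrays sharing a single shape.
    Raw acquisitions are 12-bit data in 16-bit containers; ``bit_depth``
    records the true dynamic range so the saturation ceiling is
    ``2**bit_depth - 1`` regardless of the container dtype.
    """

    well: str
    field: int
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    bit_depth: int = 12

    def __post_init__(self) -> None:
        shapes = {role: arr.shape for role, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ShapeMismatchError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        role = next(iter(self.channels))
        return self.channels[role].shape

    @property
    def saturation_ceiling(self) -> int:
        return 2**self.bit_depth - 1
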