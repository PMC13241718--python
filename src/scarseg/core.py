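"""Core containers shared across the toolkit.

A :class:`SliceRecord` bundles one short-axis image with its voxel geometry
and (optionally) the myocardium / scar / exclusion masks.  Masks are plain
boolean numpy arrays on the image grid; coordinates are 0-based ``(row, col)``
and boxes elsewhere in the package use the half-open convention
``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["VoxelGeometry", "SliceRecord", "as_bool_mask"]


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


def as_bool_mask(mask: np.ndarray, shape: Optional[tuple] = None) -> np.ndarray:
    """Coerce ``mask`` to a boolean array, optionally checking its shape."""
    out = np.asarray(mask)
    if out.dtype != bool:
        out = out.astype(bool)
    if shape is not None and out.shape != tuple(shape):
        raise ValidationError(
            f"mask shape {out.shape} does not match image grid {tuple(shape)}"
        )
    return out


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel dimensions of one slice, in millimetres.

    ``thickness_mm`` is the through-plane extent used for volume and mass
    integration (slice gap, if any, is the caller's concern).
    """

    row_spacing_mm: float
    col_spacing_mm: float
    thickness_mm: float

    def __post_init__(self) -> None:
        for name in ("row_spacing_mm", "col_spacing_mm", "thickness_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.row_spacing_mm * self.col_spacing_mm

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_area_mm2 * self.thickness_mm


@dataclass
class SliceRecord:
    """One short-axis LGE slice with geometry and optional ground-truth masks."""

    image: np.ndarray
    geometry: VoxelGeometry
    myo_mask: Optional[np.ndarray] = None
    scar_mask: Optional[np.ndarray] = None
    exclusion_mask: Optional[np.ndarray] = None
    subject_id: str = "subject-0"
    slice_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {self.image.shape}")
        shape = self.image.shape
        for name in ("myo_mask", "scar_mask", "exclusion_mask"):
            m = getattr(self, name)
            if m is not None:
                setattr(self, name, as_bool_mask(m, shape))
        if self.myo_mask is not None and self.scar_mask is not None:
            if np.any(self.scar_mask & ~self.myo_mask):
                raise ValidationError("scar_mask must be contained in myo_mask")

    @property
    def shape(self) -> tuple:
        return self.image.shape

    def with_(self, **changes) -> "SliceRecord":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **changes)
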