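"""Slice standardization: resampling to the model grid and per-slice
intensity normalization.

Images are resampled bicubically to a square target grid while preserving
the physical aspect ratio (both axes scaled by the same mm-per-pixel
factor, shorter axis padded symmetrically with the background value);
masks follow with nearest-neighbour interpolation so they stay binary.
Intensities are clipped at the 0.1st/99.9th percentiles and z-scored,
independently for every slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize

from .core import SliceRecord, ValidationError, VoxelGeometry

__all__ = ["PreprocessConfig", "resample_to_grid", "normalize_intensity", "preprocess"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 256
    clip_lo: float = 0.1
    clip_hi: float = 99.9

    def __post_init__(self) -> None:
        if not 0 <= self.clip_lo < self.clip_hi <= 100:
            raise ValidationError(
                f"percentiles must satisfy 0 <= lo < hi <= 100, got "
                f"({self.clip_lo}, {self.clip_hi})"
            )
        if self.target_size < 16:
            raise ValidationError("target_size must be >= 16")


def _resize_image(img: np.ndarray, shape, order: int) -> np.ndarray:
    # plain bicubic in both directions (no anti-aliasing pre-blur), matching
    # the stated interpolation scheme
    return resize(
        img.astype(float),
        shape,
        order=order,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )


def _resize_mask(mask: np.ndarray, shape) -> np.ndarray:
    out = resize(
        mask.astype(float), shape, order=0, mode="constant", cval=0.0,
        anti_aliasing=False, preserve_range=True,
    )
    return out > 0.5


def resample_to_grid(rec: SliceRecord, config: PreprocessConfig = PreprocessConfig()) -> SliceRecord:
    """Resample a slice to ``target_size x target_size`` preserving physical
    extent and aspect ratio.

    The output spacing is the same along both axes: the larger physical
    extent divided by the target size.  The shorter axis is padded
    symmetrically with the clipped minimum of the image.
    """
    if rec.geometry is None:
        raise ValidationError(
            "resample_to_grid requires voxel geometry; supply pixel spacing"
        )
    t = config.target_size
    rows, cols = rec.image.shape
    g = rec.geometry
    h_mm = rows * g.row_spacing_mm
    w_mm = cols * g.col_spacing_mm
    new_sp = max(h_mm, w_mm) / t
    if (
        rows == cols == t
        and abs(g.row_spacing_mm - new_sp) < 1e-12
        and abs(g.col_spacing_mm - new_sp) < 1e-12
    ):
        return rec  # already on the target grid
    new_rows = max(1, int(round(h_mm / new_sp)))
    new_cols = max(1, int(round(w_mm / new_sp)))
    img = _resize_image(rec.image, (new_rows, new_cols), order=3)
    pad_r = t - new_rows
    pad_c = t - new_cols
    pad = ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2))
    fill = float(img.min())
    img = np.pad(img, pad, mode="constant", constant_values=fill)

    def handle_mask(m: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if m is None:
            return None
        mm = _resize_mask(m, (new_rows, new_cols))
        return np.pad(mm, pad, mode="constant", constant_values=False)

    return rec.with_(
        image=img,
        geometry=VoxelGeometry(new_sp, new_sp, g.thickness_mm),
        myo_mask=handle_mask(rec.myo_mask),
        scar_mask=handle_mask(rec.scar_mask),
        exclusion_mask=handle_mask(rec.exclusion_mask),
    )


def normalize_intensity(rec: SliceRecord, config: PreprocessConfig = PreprocessConfig()) -> SliceRecord:
    """Percentile-clip then z-score one slice (population SD).

    A constant slice cannot be z-scored; it maps to all zeros with a logged
    warning.
    """
    img = rec.image.astype(float)
    lo, hi = np.percentile(img, [config.clip_lo, config.clip_hi])
    img = np.clip(img, lo, hi)
    sd = img.std()  # population (1/N) convention
    if sd == 0:
        log.warning(
            "normalize_intensity: constant slice (subject %s, slice %d); returning zeros",
            rec.subject_id, rec.slice_index,
        )
        return rec.with_(image=np.zeros_like(img))
    return rec.with_(image=(img - img.mean()) / sd)


def preprocess(rec: SliceRecord, config: PreprocessConfig = PreprocessConfig()) -> SliceRecord:
    """Resample to the model grid, then normalize intensity (in that order)."""
    return normalize_intensity(resample_to_grid(rec, config), config)
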