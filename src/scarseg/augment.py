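"""Training-time augmentation: joint spatial warps of image–mask pairs and
scanner-artifact intensity corruptions.

Each sample draws an independent :class:`TransformPlan`: CLAHE is applied
to every sample, flips and gamma modulation at probability 0.5, and all
other transforms (rotation ±15°, isotropic scaling ±10%, affine shear,
elastic deformation on a 7×7 control grid with up to 7.5 mm displacement,
third-order polynomial bias fields with coefficients up to 0.5, Gaussian
noise with σ ∈ [0, 0.1], mild Gaussian blur) at probability 0.3.  Spatial
transforms warp the image bicubically and every mask with
nearest-neighbour sampling through the *same* coordinate mapping, so masks
stay binary and containment relations survive.  Plans serialize to JSON
and replay exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_adapthist

from .core import ValidationError, VoxelGeometry

__all__ = ["AugmentConfig", "TransformPlan", "sample_transform", "apply_spatial", "apply_intensity"]


@dataclass(frozen=True)
class AugmentConfig:
    rot_deg_max: float = 15.0
    scale_frac_max: float = 0.10
    shear_deg_max: float = 8.0  # magnitude unstated upstream; configurable
    elastic_grid: int = 7
    elastic_disp_mm_max: float = 7.5
    bias_order: int = 3
    bias_coeff_max: float = 0.5
    noise_sd_range: Tuple[float, float] = (0.0, 0.1)
    blur_sigma_range: Tuple[float, float] = (0.0, 1.0)
    gamma_log_range: float = 0.3
    clahe_tiles: int = 8
    clahe_clip: float = 0.02
    p_clahe: float = 1.0
    p_flip: float = 0.5
    p_gamma: float = 0.5
    p_other: float = 0.3

    def __post_init__(self) -> None:
        for name in ("p_clahe", "p_flip", "p_gamma", "p_other"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if min(self.rot_deg_max, self.scale_frac_max, self.shear_deg_max,
               self.elastic_disp_mm_max, self.bias_coeff_max, self.gamma_log_range) < 0:
            raise ValidationError("augmentation magnitudes must be non-negative")


@dataclass
class TransformPlan:
    """A fully materialized, replayable augmentation draw."""

    flip_h: bool = False
    flip_v: bool = False
    rot_deg: Optional[float] = None
    scale: Optional[float] = None
    shear_deg: Optional[float] = None
    elastic_disp_mm: Optional[list] = None  # (grid, grid, 2) nested lists
    bias_coeffs: Optional[list] = None
    noise_sd: Optional[float] = None
    noise_seed: int = 0
    blur_sigma: Optional[float] = None
    gamma: Optional[float] = None
    clahe: bool = False
    clahe_tiles: int = 8
    clahe_clip: float = 0.02

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TransformPlan":
        return cls(**json.loads(text))

    @property
    def has_warp(self) -> bool:
        return any(
            v is not None for v in (self.rot_deg, self.scale, self.shear_deg, self.elastic_disp_mm)
        )


def sample_transform(config: AugmentConfig, seed: int = 0) -> TransformPlan:
    """Draw one plan: each transform is included independently with its
    configured probability; included magnitudes are uniform in their ranges."""
    rng = np.random.default_rng(seed)
    plan = TransformPlan(clahe_tiles=config.clahe_tiles, clahe_clip=config.clahe_clip)
    plan.flip_h = bool(rng.random() < config.p_flip)
    plan.flip_v = bool(rng.random() < config.p_flip)
    if rng.random() < config.p_other and config.rot_deg_max > 0:
        plan.rot_deg = float(rng.uniform(-config.rot_deg_max, config.rot_deg_max))
    if rng.random() < config.p_other and config.scale_frac_max > 0:
        plan.scale = float(rng.uniform(1 - config.scale_frac_max, 1 + config.scale_frac_max))
    if rng.random() < config.p_other and config.shear_deg_max > 0:
        plan.shear_deg = float(rng.uniform(-config.shear_deg_max, config.shear_deg_max))
    if rng.random() < config.p_other and config.elastic_disp_mm_max > 0:
        disp = rng.uniform(
            -config.elastic_disp_mm_max,
            config.elastic_disp_mm_max,
            size=(config.elastic_grid, config.elastic_grid, 2),
        )
        plan.elastic_disp_mm = disp.tolist()
    if rng.random() < config.p_other and config.bias_coeff_max > 0:
        n_terms = (config.bias_order + 1) * (config.bias_order + 2) // 2
        plan.bias_coeffs = rng.uniform(-config.bias_coeff_max, config.bias_coeff_max, n_terms).tolist()
    if rng.random() < config.p_other and config.noise_sd_range[1] > 0:
        plan.noise_sd = float(rng.uniform(*config.noise_sd_range))
        plan.noise_seed = int(rng.integers(0, 2**31 - 1))
    if rng.random() < config.p_other and config.blur_sigma_range[1] > 0:
        plan.blur_sigma = float(rng.uniform(*config.blur_sigma_range))
    if rng.random() < config.p_gamma and config.gamma_log_range > 0:
        plan.gamma = float(np.exp(rng.uniform(-config.gamma_log_range, config.gamma_log_range)))
    plan.clahe = bool(rng.random() < config.p_clahe)
    return plan


def _inverse_coords(plan: TransformPlan, shape, geometry: Optional[VoxelGeometry]):
    """Output-to-input coordinate map combining affine and elastic parts."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    out = np.stack([rr - cy, cc - cx])  # (2, rows, cols), centred

    theta = np.deg2rad(plan.rot_deg or 0.0)
    s = plan.scale if plan.scale is not None else 1.0
    sh = np.tan(np.deg2rad(plan.shear_deg or 0.0))
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, sh], [0.0, 1.0]])
    fwd = rot @ (s * np.eye(2)) @ shear
    inv = np.linalg.inv(fwd)
    coords = np.tensordot(inv, out, axes=(1, 0))
    coords[0] += cy
    coords[1] += cx

    if plan.elastic_disp_mm is not None:
        disp = np.asarray(plan.elastic_disp_mm, dtype=float)  # (g, g, 2), mm
        sp_r = geometry.row_spacing_mm if geometry is not None else 1.0
        sp_c = geometry.col_spacing_mm if geometry is not None else 1.0
        g = disp.shape[0]
        zoom = (rows / g, cols / g)
        dr = ndimage.zoom(disp[..., 0] / sp_r, zoom, order=3, mode="nearest")
        dc = ndimage.zoom(disp[..., 1] / sp_c, zoom, order=3, mode="nearest")
        coords[0] += dr[:rows, :cols]
        coords[1] += dc[:rows, :cols]
    return coords


def apply_spatial(
    image: np.ndarray,
    masks: Dict[str, Optional[np.ndarray]],
    plan: TransformPlan,
    geometry: Optional[VoxelGeometry] = None,
) -> Tuple[np.ndarray, Dict[str, Optional[np.ndarray]]]:
    """Warp image (bicubic) and masks (nearest-neighbour) through one shared
    coordinate mapping.  An identity plan returns the inputs bit-identical."""
    img = np.asarray(image, dtype=float)
    out_masks: Dict[str, Optional[np.ndarray]] = {}
    for k, m in masks.items():
        out_masks[k] = None if m is None else np.asarray(m, dtype=bool)

    if plan.flip_h:
        img = img[:, ::-1]
        out_masks = {k: (m[:, ::-1] if m is not None else None) for k, m in out_masks.items()}
    if plan.flip_v:
        img = img[::-1, :]
        out_masks = {k: (m[::-1, :] if m is not None else None) for k, m in out_masks.items()}

    if not plan.has_warp:
        return img.copy(), {k: (m.copy() if m is not None else None) for k, m in out_masks.items()}

    coords = _inverse_coords(plan, img.shape, geometry)
    warped = ndimage.map_coordinates(img, coords, order=3, mode="reflect")
    out = {}
    for k, m in out_masks.items():
        if m is None:
            out[k] = None
        else:
            out[k] = ndimage.map_coordinates(
                m.astype(np.uint8), coords, order=0, mode="constant", cval=0
            ).astype(bool)
    return warped, out


def _bias_surface(coeffs, shape, order: int = 3) -> np.ndarray:
    rows, cols = shape
    y = np.linspace(-1.0, 1.0, rows)[:, None]
    x = np.linspace(-1.0, 1.0, cols)[None, :]
    poly = np.zeros(shape)
    idx = 0
    for total in range(order + 1):
        for i in range(total + 1):
            j = total - i
            poly = poly + coeffs[idx] * (x**i) * (y**j)
            idx += 1
    return np.exp(poly)


def _rescale01(img: np.ndarray) -> Tuple[np.ndarray, float, float]:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img), lo, hi
    return (img - lo) / (hi - lo), lo, hi


def apply_intensity(image: np.ndarray, plan: TransformPlan) -> np.ndarray:
    """Apply intensity corruptions in fixed order:
    bias field → blur → noise → gamma → CLAHE.  Masks are never touched."""
    img = np.asarray(image, dtype=float).copy()
    if plan.bias_coeffs is not None:
        img = img * _bias_surface(plan.bias_coeffs, img.shape)
    if plan.blur_sigma is not None and plan.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, plan.blur_sigma, mode="reflect")
    if plan.noise_sd is not None and plan.noise_sd > 0:
        rng = np.random.default_rng(plan.noise_seed)
        img = img + rng.normal(0.0, plan.noise_sd, img.shape)
    if plan.gamma is not None and plan.gamma != 1.0:
        x, lo, hi = _rescale01(img)
        if hi > lo:
            img = lo + (hi - lo) * np.power(x, plan.gamma)
    if plan.clahe:
        x, lo, hi = _rescale01(img)
        if hi > lo:
            k = max(2, img.shape[0] // plan.clahe_tiles)
            eq = equalize_adapthist(x, kernel_size=k, clip_limit=plan.clahe_clip)
            img = lo + (hi - lo) * eq
    return img
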