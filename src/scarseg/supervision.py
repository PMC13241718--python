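"""Uncertainty-aware supervision: Gaussian soft labels and the composite
Dice + BCE + KL training objective.

The total loss is

    L_total = λ_Dice · L_Dice + λ_BCE · L_BCE + λ_KL · L_KL

with

    L_Dice = 1 − (2 Σ p_i g_i + ε) / (Σ p_i + Σ g_i + ε)
    L_BCE  = −(1/N) Σ [ g_i log p_i + (1 − g_i) log(1 − p_i) ]
    L_KL   = Σ s_i log( s_i / (p_i + ε) )

where ``p_i`` is the predicted scar probability at pixel i, ``g_i`` the
binary ground truth, and ``s_i`` a soft label obtained by Gaussian-blurring
the binary mask (σ = 2 by default), which encodes boundary uncertainty at
the scar–myocardium interface.  The KL term is applied to the scar-channel
map exactly as written (the maps are not normalized distributions, so it
may be negative).  Default weights λ_BCE = 0.62, λ_Dice = 0.60,
λ_KL = 0.64.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ValidationError

__all__ = [
    "LossConfig",
    "make_soft_labels",
    "dice_loss",
    "bce_loss",
    "kl_loss",
    "total_loss",
    "total_loss_grad",
]


@dataclass(frozen=True)
class LossConfig:
    lambda_dice: float = 0.60
    lambda_bce: float = 0.62
    lambda_kl: float = 0.64
    sigma: float = 2.0
    epsilon: float = 1e-6
    normalize_lambdas: bool = False
    # "sum" is the KL divergence exactly as written above; "mean" divides by
    # the pixel count N so the three terms share a per-pixel scale, the
    # normalization that keeps the composite objective stable in training.
    kl_reduction: str = "sum"

    def __post_init__(self) -> None:
        if min(self.lambda_dice, self.lambda_bce, self.lambda_kl) < 0:
            raise ValidationError("loss weights must be non-negative")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.kl_reduction not in ("sum", "mean"):
            raise ValidationError("kl_reduction must be 'sum' or 'mean'")

    @property
    def lambdas(self) -> Tuple[float, float, float]:
        lams = (self.lambda_dice, self.lambda_bce, self.lambda_kl)
        if self.normalize_lambdas:
            s = sum(lams)
            if s > 0:
                lams = tuple(v / s for v in lams)
        return lams


def _check_shapes(p: np.ndarray, g: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def make_soft_labels(g: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian-blur a binary mask into soft labels in [0, 1].

    Uses a normalized kernel with reflective boundaries truncated at 4σ, so
    label mass is conserved away from the image border; σ = 0 returns the
    mask unchanged (as float).
    """
    g = np.asarray(g, dtype=float)
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    if sigma == 0:
        return g.copy()
    return np.clip(gaussian_filter(g, sigma=sigma, mode="reflect", truncate=4.0), 0.0, 1.0)


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> float:
    p, g = _check_shapes(p, g)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def bce_loss(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> float:
    p, g = _check_shapes(p, g)
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)))


def kl_loss(s: np.ndarray, p: np.ndarray, eps: float = 1e-6, reduction: str = "sum") -> float:
    """Pointwise Σ s_i log(s_i / (p_i + ε)); terms with s_i = 0 contribute 0.

    ``reduction="mean"`` divides by N (per-pixel scale, used in training)."""
    s, p = _check_shapes(s, p)
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = s[nz] * (np.log(s[nz]) - np.log(p[nz] + eps))
    total = float(out.sum())
    return total / s.size if reduction == "mean" else total


def total_loss(
    p: np.ndarray, g: np.ndarray, config: LossConfig = LossConfig()
) -> Tuple[float, Dict[str, float]]:
    """Composite loss; soft labels are generated internally from ``g`` with
    ``config.sigma``.  Returns (total, per-component breakdown)."""
    p, g = _check_shapes(p, g)
    lam_d, lam_b, lam_k = config.lambdas
    s = make_soft_labels(g, config.sigma)
    parts = {
        "dice": dice_loss(p, g, config.epsilon),
        "bce": bce_loss(p, g, config.epsilon),
        "kl": kl_loss(s, p, config.epsilon, config.kl_reduction),
    }
    total = lam_d * parts["dice"] + lam_b * parts["bce"] + lam_k * parts["kl"]
    return float(total), parts


def total_loss_grad(
    p: np.ndarray, g: np.ndarray, config: LossConfig = LossConfig()
) -> np.ndarray:
    """Analytic gradient of the composite loss with respect to ``p``.

    The BCE gradient is evaluated on the clamped probabilities and set to
    zero where clamping is active (the clamp is flat there).
    """
    p, g = _check_shapes(p, g)
    eps = config.epsilon
    lam_d, lam_b, lam_k = config.lambdas
    s = make_soft_labels(g, config.sigma)
    n = p.size

    denom = float(p.sum() + g.sum()) + eps
    numer = 2.0 * float((p * g).sum()) + eps
    grad_dice = -(2.0 * g * denom - numer) / denom**2

    pc = np.clip(p, eps, 1.0 - eps)
    grad_bce = -(g / pc - (1.0 - g) / (1.0 - pc)) / n
    grad_bce[(p < eps) | (p > 1.0 - eps)] = 0.0

    grad_kl = -s / (p + eps)
    if config.kl_reduction == "mean":
        grad_kl = grad_kl / n

    return lam_d * grad_dice + lam_b * grad_bce + lam_k * grad_kl
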