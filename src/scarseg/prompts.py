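"""Box and point prompts that condition an interactive segmentation.

Boxes use the half-open convention ``(r0, c0, r1, c1)`` with
``[r0, r1) x [c0, c1)``; points are ``(row, col)`` foreground pixels.
Prompt augmentation (random box shift/expansion, 2–10 positive points)
mirrors the variability of human box placement and is used both during
training and in robustness evaluations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ValidationError

__all__ = [
    "Prompt",
    "bbox_from_mask",
    "augment_box",
    "sample_points",
    "make_prompt",
    "box_iou",
]

Box = Tuple[int, int, int, int]

STRATEGIES = ("box_only", "points_only", "box_and_points", "detector")


@dataclass
class Prompt:
    box: Optional[Box] = None
    points: Optional[List[Tuple[int, int]]] = None
    strategy: str = "box_only"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.box is not None:
            r0, c0, r1, c1 = self.box
            if not (r0 < r1 and c0 < c1):
                raise ValidationError(f"degenerate box {self.box}")
        needs_box = self.strategy in ("box_only", "box_and_points", "detector")
        needs_points = self.strategy in ("points_only", "box_and_points")
        if needs_box and self.box is None:
            raise ValidationError(f"strategy {self.strategy!r} requires a box")
        if needs_points and not self.points:
            raise ValidationError(f"strategy {self.strategy!r} requires points")
        if self.strategy == "box_only":
            self.points = None
        if self.strategy == "points_only":
            self.box = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "box": list(self.box) if self.box is not None else None,
                "points": [list(p) for p in self.points] if self.points else None,
                "strategy": self.strategy,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Prompt":
        d = json.loads(text)
        box = tuple(d["box"]) if d.get("box") else None
        pts = [tuple(p) for p in d["points"]] if d.get("points") else None
        return cls(box=box, points=pts, strategy=d.get("strategy", "box_only"))


def bbox_from_mask(
    mask: np.ndarray, margin_px: int = 2, grid_shape: Optional[Tuple[int, int]] = None
) -> Box:
    """Minimal enclosing rectangle of the mask foreground, expanded by a
    margin on each side and clamped to the grid.

    Multi-blob masks get one union box (mask-level, not per component).
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValidationError("bbox_from_mask: mask is empty")
    shape = grid_shape or m.shape
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0 = max(0, int(rows[0]) - margin_px)
    c0 = max(0, int(cols[0]) - margin_px)
    r1 = min(shape[0], int(rows[-1]) + 1 + margin_px)
    c1 = min(shape[1], int(cols[-1]) + 1 + margin_px)
    return (r0, c0, r1, c1)


def augment_box(
    box: Box,
    max_shift_px: int = 10,
    max_expand_frac: float = 0.20,
    seed: int = 0,
    grid_shape: Optional[Tuple[int, int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Box:
    """Randomly shift (one integer offset pair, within ±max_shift_px) and
    expand (uniform factor in [1, 1+max_expand_frac], about the centre) a
    box, clamping to the grid; the result is never empty."""
    if rng is None:
        rng = np.random.default_rng(seed)
    r0, c0, r1, c1 = box
    if max_shift_px > 0:
        dr = int(rng.integers(-max_shift_px, max_shift_px + 1))
        dc = int(rng.integers(-max_shift_px, max_shift_px + 1))
        r0, r1, c0, c1 = r0 + dr, r1 + dr, c0 + dc, c1 + dc
    if max_expand_frac > 0:
        f = 1.0 + rng.uniform(0.0, max_expand_frac)
        rc, cc = (r0 + r1) / 2.0, (c0 + c1) / 2.0
        hh, hw = (r1 - r0) / 2.0 * f, (c1 - c0) / 2.0 * f
        r0, r1 = int(round(rc - hh)), int(round(rc + hh))
        c0, c1 = int(round(cc - hw)), int(round(cc + hw))
    if grid_shape is not None:
        r0 = max(0, min(r0, grid_shape[0] - 1))
        c0 = max(0, min(c0, grid_shape[1] - 1))
        r1 = max(r0 + 1, min(r1, grid_shape[0]))
        c1 = max(c0 + 1, min(c1, grid_shape[1]))
    if r1 <= r0:
        r1 = r0 + 1
    if c1 <= c0:
        c1 = c0 + 1
    return (r0, c0, r1, c1)


def sample_points(
    mask: np.ndarray,
    n_range: Sequence[int] = (2, 10),
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[int, int]]:
    """Sample positive points uniformly (without replacement) from the mask
    foreground; the count is uniform in ``n_range`` capped at the number of
    foreground pixels."""
    m = np.asarray(mask, dtype=bool)
    fg = np.argwhere(m)
    if fg.shape[0] == 0:
        raise ValidationError("sample_points: mask is empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = int(n_range[0]), int(n_range[-1])
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    n = min(n, fg.shape[0])
    idx = rng.choice(fg.shape[0], size=n, replace=False)
    return [(int(r), int(c)) for r, c in fg[idx]]


def make_prompt(
    mask: Optional[np.ndarray] = None,
    strategy: str = "box_and_points",
    seed: int = 0,
    detector_box: Optional[Box] = None,
    margin_px: int = 2,
    n_range: Sequence[int] = (2, 10),
    grid_shape: Optional[Tuple[int, int]] = None,
) -> Prompt:
    """Build a prompt for the given strategy from a ground-truth mask, or
    pass through an externally detected box (abstract detector seam)."""
    rng = np.random.default_rng(seed)
    if strategy == "detector":
        if detector_box is None:
            raise ValidationError("detector strategy requires detector_box")
        return Prompt(box=detector_box, strategy="detector")
    if mask is None:
        raise ValidationError(f"strategy {strategy!r} requires a mask")
    box = None
    points = None
    if strategy in ("box_only", "box_and_points"):
        box = bbox_from_mask(mask, margin_px=margin_px, grid_shape=grid_shape)
    if strategy in ("points_only", "box_and_points"):
        points = sample_points(mask, n_range=n_range, rng=rng)
    return Prompt(box=box, points=points, strategy=strategy)


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open boxes."""
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    ih = max(0, min(ar1, br1) - max(ar0, br0))
    iw = max(0, min(ac1, bc1) - max(ac0, bc0))
    inter = ih * iw
    area_a = (ar1 - ar0) * (ac1 - ac0)
    area_b = (br1 - br0) * (bc1 - bc0)
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0
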