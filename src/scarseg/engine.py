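"""Backbone-agnostic prompt-conditioned segmentation engine.

Any backbone satisfying :class:`BackboneContract` — ``forward(image,
prompt) -> probability map`` over named, freezable parameter groups — can
be trained here with the composite soft-label loss, AdamW-style decoupled
weight decay, stepwise learning-rate halving (×0.5 every 10 epochs), and
early stopping on validation Dice (patience 20, best checkpoint
restored).  Prompts are regenerated every epoch with prompt augmentation
(box shift ±10 px, expansion up to 20%, 2–10 positive points) so the
model learns to be resilient to variable human box placement.

The built-in :class:`TinyPromptNet` is a desk-scale surrogate honoring
the contract: a per-pixel multilayer perceptron over image features
(intensity, smoothed intensity) and rendered prompt channels (filled box,
σ=2 Gaussian point heatmap, point-proximity decay).  Its ``prompt`` gain
group is frozen by default, mirroring a frozen prompt encoder.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import SliceRecord, ValidationError
from .prompts import Prompt, augment_box, bbox_from_mask, make_prompt, sample_points
from .supervision import LossConfig, total_loss, total_loss_grad

__all__ = [
    "TrainConfig",
    "TinyPromptNet",
    "lr_at_epoch",
    "train",
    "predict",
    "refine_mask",
    "evaluate_dsc",
]


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    weight_decay: float = 1e-2
    lr_halving_period_epochs: int = 10
    max_epochs: int = 100
    early_stop_patience_epochs: int = 20
    batch_size: int = 8
    seed: int = 0
    # training uses the per-pixel KL reduction (the stability normalization);
    # the printed sum form remains the default for standalone loss analytics
    loss: LossConfig = field(default_factory=lambda: LossConfig(kl_reduction="mean"))
    freeze: Tuple[str, ...] = ("prompt",)
    prompt_strategy: str = "box_and_points"
    box_shift_px: int = 10
    box_expand_frac: float = 0.20
    n_points_range: Tuple[int, int] = (2, 10)

    def __post_init__(self) -> None:
        if min(self.lr0, self.lr_halving_period_epochs, self.max_epochs,
               self.early_stop_patience_epochs, self.batch_size) <= 0:
            raise ValidationError("training hyperparameters must be positive")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be non-negative")
        if self.early_stop_patience_epochs > self.max_epochs:
            raise ValidationError("patience must not exceed max_epochs")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stepwise decay: lr0 · 0.5^⌊epoch / period⌋ (epoch is 0-based)."""
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    return config.lr0 * 0.5 ** (epoch // config.lr_halving_period_epochs)


def _point_distance(shape, points) -> np.ndarray:
    ind = np.ones(shape, dtype=bool)
    for r, c in points:
        ind[int(r), int(c)] = False
    return ndimage.distance_transform_edt(ind)


class TinyPromptNet:
    """Small per-pixel MLP conditioned on rendered prompt channels.

    Image features: raw and Gaussian-smoothed intensity.  Prompt features:
    a filled box channel, the intensity z-scored against the in-box
    statistics (scar is typically the brightest structure inside its own
    box), a σ=2 Gaussian point heatmap, and two point-proximity decays
    (fixed scale and box-diagonal scale, so point influence adapts to
    lesion size).  Parameter groups: ``encoder`` (input layer),
    ``decoder`` (output layer), ``prompt`` (gains on the box, heatmap and
    proximity channel families; frozen by default, mirroring a frozen
    prompt encoder).
    """

    N_FEATURES = 7
    # feature column -> prompt gain index (None = image feature)
    _GAIN_OF = (None, None, 0, 0, 1, 2, 2)
    name = "tiny-promptnet"

    def __init__(self, n_hidden: int = 48, seed: int = 0, init_scale: float = 0.15):
        # small-magnitude init keeps tanh units unsaturated, which makes the
        # short desk-scale training runs much less init-sensitive
        rng = np.random.default_rng(seed)
        self.n_hidden = n_hidden
        self.params: Dict[str, np.ndarray] = {
            "encoder.W1": rng.normal(0.0, init_scale, (self.N_FEATURES, n_hidden)),
            "encoder.b1": np.zeros(n_hidden),
            "decoder.W2": rng.normal(0.0, init_scale, n_hidden),
            "decoder.b2": np.zeros(1),
            "prompt.gain": np.ones(3),
        }

    # -- feature rendering --------------------------------------------------
    def _features(self, image: np.ndarray, prompt: Optional[Prompt]):
        img = np.asarray(image, dtype=float)
        shape = img.shape
        box_chan = np.zeros(shape)
        inbox_rel = np.zeros(shape)
        heat = np.zeros(shape)
        prox = np.zeros(shape)
        prox_scaled = np.zeros(shape)
        diag = float(np.hypot(*shape))
        if prompt is not None and prompt.box is not None:
            r0, c0, r1, c1 = prompt.box
            r0, c0 = max(r0, 0), max(c0, 0)
            box_chan[r0:r1, c0:c1] = 1.0
            sub = img[r0:r1, c0:c1]
            if sub.size:
                inbox_rel = box_chan * (img - sub.mean()) / (sub.std() + 1e-6)
                diag = float(np.hypot(r1 - r0, c1 - c0))
        if prompt is not None and prompt.points:
            d = _point_distance(shape, prompt.points)
            heat = np.exp(-(d**2) / (2.0 * 2.0**2))  # σ = 2 heatmap
            prox = np.exp(-d / 8.0)
            prox_scaled = np.exp(-d / (0.35 * diag))
        gain = self.params["prompt.gain"]
        raw = np.stack(
            [
                img,
                ndimage.gaussian_filter(img, 2.0, mode="reflect"),
                box_chan,
                inbox_rel,
                heat,
                prox,
                prox_scaled,
            ],
            axis=-1,
        ).reshape(-1, self.N_FEATURES)
        scale = np.array(
            [1.0 if g is None else gain[g] for g in self._GAIN_OF]
        )
        return raw * scale, raw

    def forward(self, image: np.ndarray, prompt: Optional[Prompt]) -> np.ndarray:
        feats, _ = self._features(image, prompt)
        p, _ = self._mlp(feats)
        return p.reshape(image.shape)

    def _mlp(self, feats: np.ndarray):
        z1 = feats @ self.params["encoder.W1"] + self.params["encoder.b1"]
        h = np.tanh(z1)
        z2 = h @ self.params["decoder.W2"] + self.params["decoder.b2"][0]
        p = 1.0 / (1.0 + np.exp(-z2))
        return p, (feats, h)

    def forward_backward(
        self, image: np.ndarray, g: np.ndarray, prompt: Optional[Prompt], loss_cfg: LossConfig
    ):
        feats, raw = self._features(image, prompt)
        p_flat, (F, h) = self._mlp(feats)
        p = p_flat.reshape(image.shape)
        loss, parts = total_loss(p, g, loss_cfg)
        dldp = total_loss_grad(p, g, loss_cfg).ravel()
        dz2 = dldp * p_flat * (1.0 - p_flat)
        grads = {
            "decoder.W2": h.T @ dz2,
            "decoder.b2": np.array([dz2.sum()]),
        }
        dh = np.outer(dz2, self.params["decoder.W2"])
        dz1 = dh * (1.0 - h**2)
        grads["encoder.W1"] = F.T @ dz1
        grads["encoder.b1"] = dz1.sum(axis=0)
        dF = dz1 @ self.params["encoder.W1"].T
        gain_grad = np.zeros(3)
        for col, g_idx in enumerate(self._GAIN_OF):
            if g_idx is not None:
                gain_grad[g_idx] += float((dF[:, col] * raw[:, col]).sum())
        grads["prompt.gain"] = gain_grad
        return loss, parts, grads

    def snapshot(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: Dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in snap.items()}


class _AdamW:
    def __init__(self, params: Dict[str, np.ndarray], weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray],
             lr: float, frozen: Sequence[str]) -> None:
        self.t += 1
        for k, g in grads.items():
            group = k.split(".", 1)[0]
            if group in frozen:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * params[k])


def _train_prompt(rec: SliceRecord, config: TrainConfig, rng: np.random.Generator) -> Prompt:
    """Per-epoch augmented prompt for one training slice."""
    mask = rec.scar_mask
    box = None
    points = None
    if config.prompt_strategy in ("box_only", "box_and_points"):
        box = bbox_from_mask(mask, margin_px=2, grid_shape=rec.shape)
        box = augment_box(
            box, config.box_shift_px, config.box_expand_frac,
            grid_shape=rec.shape, rng=rng,
        )
    if config.prompt_strategy in ("points_only", "box_and_points"):
        points = sample_points(mask, config.n_points_range, rng=rng)
    return Prompt(box=box, points=points, strategy=config.prompt_strategy)


def eval_prompt(rec: SliceRecord, strategy: str, seed: int = 0) -> Prompt:
    """Clean (un-jittered) prompt for evaluation."""
    return make_prompt(rec.scar_mask, strategy=strategy, seed=seed, grid_shape=rec.shape)


def _dsc(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / (sa + sb)


def evaluate_dsc(
    backbone, records: Sequence[SliceRecord], strategy: str = "box_and_points",
    seed: int = 0, prompts: Optional[Sequence[Prompt]] = None, threshold: float = 0.5,
) -> float:
    """Mean Dice of thresholded predictions against ground truth."""
    scores = []
    for i, rec in enumerate(records):
        prompt = prompts[i] if prompts is not None else eval_prompt(rec, strategy, seed + i)
        _, mask = predict(backbone, rec, prompt, threshold)
        scores.append(_dsc(mask, rec.scar_mask))
    return float(np.mean(scores))


def train(
    backbone,
    train_set: Sequence[SliceRecord],
    val_set: Sequence[SliceRecord],
    config: TrainConfig = TrainConfig(),
    val_scorer: Optional[Callable] = None,
) -> Tuple[object, List[dict]]:
    """Optimize the backbone under the composite loss with the stepwise
    schedule and early stopping on validation Dice.

    ``val_scorer(backbone, val_set, epoch) -> float`` can be injected (e.g.
    for scripted traces); by default validation Dice uses clean prompts of
    the configured strategy.  Returns the backbone restored to its best
    validation checkpoint, plus the per-epoch history.
    """
    train_set = [r for r in train_set if r.scar_mask is not None and r.scar_mask.any()]
    if not train_set:
        raise ValidationError("train(): empty training set")
    if val_scorer is None and not val_set:
        raise ValidationError("train(): empty validation set")
    rng = np.random.default_rng(config.seed)
    opt = _AdamW(backbone.params, config.weight_decay)
    frozen = tuple(config.freeze)
    history: List[dict] = []
    best_dsc = -np.inf
    best_epoch = 0
    best_snap = backbone.snapshot()

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch - 1)
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        epoch_parts = {"dice": 0.0, "bce": 0.0, "kl": 0.0}
        acc: Optional[Dict[str, np.ndarray]] = None
        n_acc = 0
        for j, idx in enumerate(order):
            rec = train_set[idx]
            prompt = _train_prompt(rec, config, rng)
            loss, parts, grads = backbone.forward_backward(
                rec.image, rec.scar_mask.astype(float), prompt, config.loss
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, slice {rec.subject_id}/"
                    f"{rec.slice_index}: parts={parts}"
                )
            epoch_loss += loss
            for k in epoch_parts:
                epoch_parts[k] += parts[k]
            if acc is None:
                acc = {k: v.copy() for k, v in grads.items()}
            else:
                for k, v in grads.items():
                    acc[k] += v
            n_acc += 1
            if n_acc == config.batch_size or j == len(order) - 1:
                opt.step(backbone.params, {k: v / n_acc for k, v in acc.items()}, lr, frozen)
                acc, n_acc = None, 0

        if val_scorer is not None:
            val_dsc = float(val_scorer(backbone, val_set, epoch))
        else:
            val_dsc = evaluate_dsc(backbone, val_set, config.prompt_strategy, seed=config.seed)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss": epoch_loss / len(train_set),
                **{k: v / len(train_set) for k, v in epoch_parts.items()},
                "val_dsc": val_dsc,
            }
        )
        if val_dsc > best_dsc + 1e-5:
            best_dsc = val_dsc
            best_epoch = epoch
            best_snap = backbone.snapshot()
        if epoch - best_epoch >= config.early_stop_patience_epochs:
            break

    backbone.restore(best_snap)
    return backbone, history


def predict(
    backbone, rec: SliceRecord, prompt: Optional[Prompt], threshold: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Probability map and its thresholded binary mask (p >= threshold)."""
    image = rec.image if isinstance(rec, SliceRecord) else np.asarray(rec, dtype=float)
    pmap = backbone.forward(image, prompt)
    return pmap, pmap >= threshold


def save_checkpoint(backbone, history: List[dict], path) -> None:
    """Persist backbone weights + training history (npz with a JSON blob)."""
    import json

    arrays = {k.replace(".", "__"): v for k, v in backbone.params.items()}
    np.savez(
        path,
        __meta__=np.frombuffer(
            json.dumps({"n_hidden": backbone.n_hidden, "history": history}).encode(),
            dtype=np.uint8,
        ),
        **arrays,
    )


def load_checkpoint(path) -> Tuple[TinyPromptNet, List[dict]]:
    import json

    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    net = TinyPromptNet(n_hidden=meta["n_hidden"])
    for k in net.params:
        net.params[k] = data[k.replace(".", "__")]
    return net, meta["history"]


# 3×3 "elliptical" structuring element; at this size the rasterized ellipse
# degenerates to the 4-connected cross.
_KERNEL = ndimage.generate_binary_structure(2, 1)


def refine_mask(mask: np.ndarray, direction: str) -> np.ndarray:
    """Single-iteration morphological shrink (erosion) or expand (dilation)."""
    m = np.asarray(mask, dtype=bool)
    if direction == "shrink":
        return ndimage.binary_erosion(m, structure=_KERNEL, border_value=0)
    if direction == "expand":
        return ndimage.binary_dilation(m, structure=_KERNEL, border_value=0)
    raise ValidationError(f"direction must be 'shrink' or 'expand', got {direction!r}")
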