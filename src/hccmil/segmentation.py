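"""Nuclei segmentation: a U-net trained with Dice loss, emitting soft
per-pixel nuclei probability heatmaps.

The heatmap is deliberately *not* thresholded anywhere downstream: soft
values carry information beyond nucleus boundaries (cytoplasm, cell shape)
that the slide classifier exploits as its fourth input channel.

Dice loss over an image with prediction p and binary truth y:

    L = 1 - 2 (sum p*y + eps) / (sum p + sum y + eps)

with eps = 1e-8 keeping the ratio defined on empty scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Tensor, no_grad, ops
from ._nn.layers import Adam, Conv2d, GroupNorm2d, Module

__all__ = ["SegPair", "Heatmap", "SegTrainConfig", "dice_loss", "UNet",
           "build_unet", "train_unet", "predict_heatmap", "dice_score"]

#: smoothing term of the Dice ratio
DICE_EPSILON = 1e-8


@dataclass
class SegPair:
    """One training example: RGB tile and its binary nuclei mask."""

    image: np.ndarray          # HxWx3 uint8
    mask: np.ndarray           # HxW in {0,1}

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask spatial dimensions differ")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must be binary")


@dataclass
class Heatmap:
    """Per-pixel nuclei probability map aligned to a tile."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


@dataclass
class SegTrainConfig:
    epsilon: float = DICE_EPSILON
    depth: int = 3             # encoder levels (including the bottleneck)
    base_channels: int = 8
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 8
    val_fraction: float = 0.2
    augment: bool = True       # horizontal/vertical flips
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def dice_loss(pred, truth, epsilon: float = DICE_EPSILON) -> float:
    """1 - 2 (sum p*y + eps) / (sum p + sum y + eps), sums over all pixels."""
    p = pred.values if isinstance(pred, Heatmap) else np.asarray(pred, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("prediction and truth shapes differ")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    sp, sy = float(p.sum()), float(y.sum())
    if sp == 0.0 and sy == 0.0:
        return 0.0          # both empty: perfect agreement
    num = 2.0 * (float((p * y).sum()) + epsilon)
    den = sp + sy + epsilon
    return 1.0 - num / den


def dice_score(pred, truth, epsilon: float = DICE_EPSILON) -> float:
    """Soft Dice overlap = 1 - dice_loss."""
    return 1.0 - dice_loss(pred, truth, epsilon)


def _dice_loss_tensor(p: Tensor, y: np.ndarray, epsilon: float) -> Tensor:
    """Differentiable Dice loss on a batch (summed over the whole batch)."""
    yt = Tensor(y.astype(np.float32))
    inter = ops.sum_all(ops.mul(p, yt))
    denom = ops.add(ops.sum_all(p), Tensor(np.float32(y.sum() + epsilon)))
    num = ops.add(ops.scale(inter, 2.0), Tensor(np.float32(2.0 * epsilon)))
    # 1 - num/den via custom small graph: use log-free division
    return _one_minus_div(num, denom)


def _one_minus_div(num: Tensor, den: Tensor) -> Tensor:
    from ._nn.tensor import make, _accumulate

    n, d = float(num.data), float(den.data)
    out = np.asarray(1.0 - n / d, dtype=np.float32)

    def backward(g):
        _accumulate(num, np.asarray(-float(g) / d, dtype=np.float32))
        _accumulate(den, np.asarray(float(g) * n / d ** 2, dtype=np.float32))

    return make(out, (num, den), backward)


# ---------------------------------------------------------------------------
# U-net
# ---------------------------------------------------------------------------

class _DoubleConv(Module):
    """conv-norm-ReLU twice; GroupNorm keeps Dice-only training away from
    the empty-prediction attractor that plain stacked convs fall into."""

    def __init__(self, rng, in_ch, out_ch):
        super().__init__()
        self.a = Conv2d(rng, in_ch, out_ch, k=3, bias=False)
        self.na = GroupNorm2d(out_ch)
        self.b = Conv2d(rng, out_ch, out_ch, k=3, bias=False)
        self.nb = GroupNorm2d(out_ch)

    def forward(self, x):
        return ops.relu(self.nb(self.b(ops.relu(self.na(self.a(x))))))


class UNet(Module):
    """Encoder-decoder with skip connections and a per-pixel sigmoid head.

    ``depth`` counts encoder levels including the bottleneck; each level
    doubles the channel width.  Input is 3-channel RGB scaled to [0, 1],
    output a 1-channel probability map of the same spatial size.
    """

    def __init__(self, config: SegTrainConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        ch = [config.base_channels * 2 ** i for i in range(config.depth)]
        self.enc = [_DoubleConv(rng, 3 if i == 0 else ch[i - 1], ch[i])
                    for i in range(config.depth)]
        self.dec = [_DoubleConv(rng, ch[i] + ch[i + 1], ch[i])
                    for i in range(config.depth - 1)]
        self.out_conv = Conv2d(rng, ch[0], 1, k=1, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        size = x.data.shape[2]
        if size % 2 ** (self.config.depth - 1):
            raise ValueError(
                f"input size {size} incompatible with depth {self.config.depth}")
        skips = []
        h = x
        for i, enc in enumerate(self.enc):
            h = enc(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = ops.maxpool2(h)
        for i in range(len(self.dec) - 1, -1, -1):
            h = ops.upsample2(h)
            h = ops.concat_channels(skips[i], h)
            h = self.dec[i](h)
        return ops.sigmoid(self.out_conv(h))


def build_unet(config: SegTrainConfig | None = None) -> UNet:
    """Construct a seeded U-net; same config and seed give identical weights."""
    return UNet(config or SegTrainConfig())


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _to_batch(pairs: list[SegPair]):
    x = np.stack([p.image.astype(np.float32).transpose(2, 0, 1) / 255.0
                  for p in pairs])
    y = np.stack([p.mask.astype(np.float32) for p in pairs])[:, None]
    return x, y


def train_unet(pairs: list[SegPair], config: SegTrainConfig | None = None,
               val_pairs: list[SegPair] | None = None):
    """Train a U-net on (image, mask) pairs with Dice loss.

    If no validation pairs are supplied, a seeded shuffle holds out
    ``val_fraction`` of the input.  Returns ``(model, history)`` where
    history records per-epoch mean training Dice loss and the soft Dice
    score on the held-out pairs (computed on unthresholded predictions).
    """
    config = config or SegTrainConfig()
    if len(pairs) < 2 and val_pairs is None:
        raise ValueError("need at least 2 pairs to split train/validation")
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if val_pairs is None:
        idx = rng.permutation(len(pairs))
        n_val = max(1, int(round(config.val_fraction * len(pairs))))
        val_pairs = [pairs[i] for i in idx[:n_val]]
        pairs = [pairs[i] for i in idx[n_val:]]
    model = build_unet(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_dice_loss": [], "val_dice": []}
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), config.batch_size):
            batch = [pairs[i] for i in order[start:start + config.batch_size]]
            x, y = _to_batch(batch)
            if config.augment:
                if rng.uniform() < 0.5:
                    x, y = x[:, :, :, ::-1].copy(), y[:, :, :, ::-1].copy()
                if rng.uniform() < 0.5:
                    x, y = x[:, :, ::-1].copy(), y[:, :, ::-1].copy()
            model.zero_grad()
            pred = model(Tensor(x))
            loss = _dice_loss_tensor(pred, y, config.epsilon)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_dice_loss"].append(float(np.mean(losses)))
        history["val_dice"].append(evaluate_dice(model, val_pairs, config.epsilon))
    return model, history


def evaluate_dice(model: UNet, pairs: list[SegPair],
                  epsilon: float = DICE_EPSILON) -> float:
    """Mean per-image soft Dice score on unthresholded predictions."""
    scores = []
    for pair in pairs:
        hm = predict_heatmap(model, pair.image)
        scores.append(dice_score(hm.values, pair.mask, epsilon))
    return float(np.mean(scores))


def predict_heatmap(model: UNet, tile: np.ndarray) -> Heatmap:
    """Soft nuclei probability map for one RGB tile (never thresholded)."""
    tile = np.asarray(tile)
    x = tile.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    with no_grad():
        out = model(Tensor(x))
    return Heatmap(out.data[0, 0])
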