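"""Multiple-instance learning core: four-channel tiles, per-tile scoring by a
MobileNetV2-style backbone, signed generalized-mean bag aggregation, threshold
classification, the piecewise probability transform, the regularized
cross-entropy objective, the MIL training loop and high-predictability tile
retrieval.

Label convention
----------------
The probability transform maps *high* activated bag scores to *low*
probabilities, so the cross-entropy drives bags labelled ``y = 1`` toward low
activated scores.  Throughout this package ``y = 1`` means *good outcome /
low risk* and the reported "risk score" of a slide is its activated
(sigmoid) aggregate score.  A bag is assigned to the high-score (high-risk)
class exactly when its activated score strictly exceeds the threshold ``t``;
a tie at ``t`` goes to the low-score class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import Tensor, no_grad, ops
from ._nn.layers import Adam, Conv2d, GroupNorm2d, Linear, Module

__all__ = [
    "Bag", "MILConfig", "BagScore", "ModelHandle",
    "assemble_four_channel", "split_four_channel", "aggregate_scores",
    "classify_bag", "transform_probability", "mil_loss",
    "build_backbone", "train_mil", "predict_slide", "rank_tiles",
]

#: clipping bound applied to probabilities before taking logs in the loss
LOG_CLIP_DELTA = 1e-7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Bag:
    """All tiles of one slide plus a single binary outcome label.

    ``label = 1`` encodes good outcome / low risk (see module docstring).
    Tiles are stored as a (n_tiles, 4, H, W) float32 array in channel order
    (R, G, B, heatmap), RGB scaled to [0, 1].  No per-tile label exists on
    this type by construction: provenance flags (e.g. which tiles carry
    simulated signal) live in ``meta`` and are never consumed by training.
    """

    slide_id: str
    tiles: np.ndarray
    label: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tiles = np.asarray(self.tiles, dtype=np.float32)
        if self.tiles.ndim != 4 or self.tiles.shape[1] != 4:
            raise ValueError("tiles must have shape (n, 4, H, W)")
        if self.tiles.shape[0] < 1:
            raise ValueError("a bag needs at least one tile")
        if self.label not in (0, 1):
            raise ValueError("bag label must be binary")

    def __len__(self) -> int:
        return self.tiles.shape[0]


@dataclass
class MILConfig:
    """Hyperparameters of the MIL classifier and its training loop."""

    aggregation_exponent: float = 3.0
    threshold: float = 0.4457
    l2_alpha: float = 0.02
    initial_lr: float = 0.0001
    lr_halving_epochs: int = 10
    bag_batch_size: int = 1
    backbone_variant: str = "tiny"
    epochs: int = 20
    power_mean: bool = False  # use (1/n sum s^p)^(1/p) instead of the plain p-norm
    seed: int = 0

    def __post_init__(self):
        if self.aggregation_exponent < 1:
            raise ValueError("aggregation exponent must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.l2_alpha < 0:
            raise ValueError("l2_alpha must be non-negative")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


@dataclass
class BagScore:
    """Per-tile scores and the derived bag-level quantities."""

    slide_id: str
    tile_scores: np.ndarray
    aggregate: float          # S, the signed p-norm of the tile scores
    activated: float          # sigmoid(S) — the slide's risk score
    prob: float               # transformed probability p_i
    predicted_class: int      # 1 iff activated > threshold (high-score class)


@dataclass
class ModelHandle:
    """Trained backbone plus its config snapshot and training history."""

    backbone: Module
    config: MILConfig
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})

    def state_dict(self) -> dict:
        return {"weights": self.backbone.state_dict(),
                "config": self.config.__dict__.copy(),
                "history": self.history}


# ---------------------------------------------------------------------------
# tile assembly
# ---------------------------------------------------------------------------

def assemble_four_channel(rgb_tile: np.ndarray, heatmap: np.ndarray) -> np.ndarray:
    """Stack an RGB tile (uint8 HxWx3) with a nuclei heatmap into (4, H, W).

    RGB is scaled to [0, 1]; the heatmap must already be in [0, 1].
    """
    rgb_tile = np.asarray(rgb_tile)
    heatmap = np.asarray(heatmap, dtype=np.float32)
    if rgb_tile.shape[:2] != heatmap.shape:
        raise ValueError("tile and heatmap spatial sizes differ")
    if heatmap.min() < 0 or heatmap.max() > 1:
        raise ValueError("heatmap values must lie in [0, 1]")
    rgb = rgb_tile.astype(np.float32) / 255.0 if rgb_tile.dtype == np.uint8 \
        else rgb_tile.astype(np.float32)
    return np.concatenate([rgb.transpose(2, 0, 1), heatmap[None]], axis=0)


def split_four_channel(tile4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`assemble_four_channel` (RGB returned as uint8)."""
    rgb = np.round(tile4[:3].transpose(1, 2, 0) * 255.0).astype(np.uint8)
    return rgb, tile4[3].copy()


# ---------------------------------------------------------------------------
# aggregation / classification / transform / loss (plain-array versions)
# ---------------------------------------------------------------------------

def aggregate_scores(scores, p: float = 3.0, power_mean: bool = False) -> float:
    """Signed generalized-mean aggregation of per-tile scores.

    S = sign(T) |T|^(1/p) with T = sum_i sign(s_i)|s_i|^p, which for
    non-negative scores (and for odd integer p) is the plain p-norm sum
    (sum s_i^p)^(1/p).  With ``power_mean`` the sum is divided by n first.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("cannot aggregate an empty score list")
    if p < 1:
        raise ValueError("aggregation exponent must be >= 1")
    t = float((np.sign(s) * np.abs(s) ** p).sum())
    if power_mean:
        t /= s.size
    return float(math.copysign(abs(t) ** (1.0 / p), t)) if t != 0 else 0.0


def classify_bag(aggregate: float, threshold: float = 0.4457) -> tuple[float, int]:
    """Sigmoid-activate the bag score and compare with the threshold.

    Returns ``(activated, predicted_class)`` with class 1 = high-score class
    iff ``activated > threshold`` (ties go to the low-score class).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    activated = float(1.0 / (1.0 + math.exp(-aggregate)))
    return activated, int(activated > threshold)


def transform_probability(s: float, t: float = 0.4457) -> float:
    """Piecewise-linear map of the activated score to a probability.

    p = ((t - s)/t + 1) * 0.5 for s <= t, and (1 - (s - t)/(1 - t)) * 0.5
    for s > t.  Continuous, strictly decreasing, p(0) = 1, p(t) = 0.5,
    p(1) = 0.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("activated score must lie in [0, 1]")
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if s <= t:
        return ((t - s) / t + 1.0) * 0.5
    return (1.0 - (s - t) / (1.0 - t)) * 0.5


def mil_loss(probs, labels, weights=None, alpha: float = 0.02,
             delta: float = LOG_CLIP_DELTA) -> float:
    """Cross-entropy over transformed bag probabilities plus L2 penalty.

    L = -(1/N) sum [y log p + (1-y) log(1-p)] + alpha * sum w^2, with the
    probabilities clipped to [delta, 1-delta] before the logs.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty batch")
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    pc = np.clip(p, delta, 1.0 - delta)
    ce = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    l2 = 0.0
    if weights is not None and alpha > 0:
        for w in weights:
            arr = w.data if isinstance(w, Tensor) else np.asarray(w, dtype=np.float64)
            l2 += float((arr ** 2).sum())
        l2 *= alpha
    return ce + l2


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class _InvertedResidual(Module):
    """MobileNetV2 inverted residual: 1x1 expand -> 3x3 depthwise -> 1x1 project."""

    def __init__(self, rng, in_ch, out_ch, stride, expand_ratio):
        super().__init__()
        hidden = max(int(round(in_ch * expand_ratio)), 4)
        self.use_res = stride == 1 and in_ch == out_ch
        self.expand = None
        if expand_ratio != 1:
            self.expand = Conv2d(rng, in_ch, hidden, k=1, padding=0, bias=False)
            self.bn0 = GroupNorm2d(hidden)
        self.dw = Conv2d(rng, hidden, hidden, k=3, stride=stride, depthwise=True,
                         bias=False)
        self.bn1 = GroupNorm2d(hidden)
        self.project = Conv2d(rng, hidden, out_ch, k=1, padding=0, bias=False)
        self.bn2 = GroupNorm2d(out_ch)

    def forward(self, x):
        h = x
        if self.expand is not None:
            h = ops.relu6(self.bn0(self.expand(h)))
        h = ops.relu6(self.bn1(self.dw(h)))
        h = self.bn2(self.project(h))
        if self.use_res:
            h = ops.add(h, x)
        return h


# MobileNetV2 (width 1.0) inverted-residual plan: (expansion t, channels c,
# repeats n, first stride s)
_MOBILENETV2_PLAN = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]

# 3-stage, width-0.25 plan for CPU-scale tests
_TINY_PLAN = [
    (1, 8, 1, 1),
    (4, 12, 1, 2),
    (4, 16, 1, 2),
]


class MobileNetBackbone(Module):
    """Per-tile scorer: inverted-residual trunk, global average pooling and a
    single-unit linear head emitting the raw tile score s_i.

    Normalization is GroupNorm rather than BatchNorm: training proceeds one
    bag at a time, where batch statistics would couple the instances of a
    bag and diverge from inference-time statistics.  Because per-sample
    normalization discards absolute intensity levels, the head additionally
    receives the globally pooled input channels (mean R, G, B and heatmap
    level of the tile) alongside the trunk features, restoring stain- and
    nuclei-abundance information.
    """

    def __init__(self, rng, plan, stem_ch, last_ch, in_channels=4):
        super().__init__()
        self.stem = Conv2d(rng, in_channels, stem_ch, k=3, stride=2, bias=False)
        self.bn_stem = GroupNorm2d(stem_ch)
        blocks = []
        ch = stem_ch
        for t, c, n, s in plan:
            for i in range(n):
                blocks.append(_InvertedResidual(rng, ch, c, s if i == 0 else 1, t))
                ch = c
        self.blocks = blocks
        self.head_conv = Conv2d(rng, ch, last_ch, k=1, padding=0, bias=False)
        self.bn_head = GroupNorm2d(last_ch)
        self.head = Linear(rng, last_ch + in_channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 4, H, W) -> (N,) raw tile scores."""
        h = ops.relu6(self.bn_stem(self.stem(x)))
        for b in self.blocks:
            h = b(h)
        h = ops.relu6(self.bn_head(self.head_conv(h)))
        h = ops.global_avg_pool(h)
        h = ops.concat_features(h, ops.global_avg_pool(x))
        h = self.head(h)
        return ops.reshape(h, (x.data.shape[0],))


def build_backbone(variant: str = "tiny", in_channels: int = 4,
                   seed: int = 0) -> MobileNetBackbone:
    """Construct a per-tile scorer.

    ``standard`` follows the published MobileNetV2 topology (width 1.0) with
    a 4-channel first convolution and a 1-unit head; ``tiny`` is a 3-stage,
    width-0.25 analogue for CPU-scale runs.
    """
    rng = np.random.default_rng(seed)
    if variant == "standard":
        return MobileNetBackbone(rng, _MOBILENETV2_PLAN, stem_ch=32, last_ch=1280,
                                 in_channels=in_channels)
    if variant == "tiny":
        return MobileNetBackbone(rng, _TINY_PLAN, stem_ch=8, last_ch=32,
                                 in_channels=in_channels)
    raise ValueError(f"unknown backbone variant: {variant!r}")


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def learning_rate_at(epoch: int, config: MILConfig) -> float:
    """Decayed learning rate: initial_lr * 0.5 ** floor(epoch / halving)."""
    return config.initial_lr * 0.5 ** (epoch // config.lr_halving_epochs)


def _bag_forward(backbone: Module, bag: Bag, config: MILConfig):
    """Differentiable bag pass: tile scores -> aggregate -> sigmoid -> p_i."""
    x = Tensor(bag.tiles)
    s = backbone(x)
    t_sum = ops.signed_power_sum(s, config.aggregation_exponent)
    if config.power_mean:
        t_sum = ops.scale(t_sum, 1.0 / len(bag))
    agg = ops.signed_root(t_sum, config.aggregation_exponent)
    act = ops.sigmoid(agg)
    prob = ops.prob_transform_op(act, config.threshold)
    return s, agg, act, prob


def train_mil(bags: list[Bag], config: MILConfig | None = None,
              backbone: Module | None = None) -> ModelHandle:
    """Train the MIL classifier on labelled bags.

    One optimization step scores all tiles of ``bag_batch_size`` bags,
    aggregates with the signed p-norm, applies sigmoid and the probability
    transform, and backpropagates the regularized cross-entropy.  The
    learning rate halves every ``lr_halving_epochs`` epochs.
    """
    config = config or MILConfig()
    labels = {b.label for b in bags}
    if labels != {0, 1}:
        raise ValueError("training requires bags from both classes")
    rng = np.random.default_rng(config.seed)
    if backbone is None:
        backbone = build_backbone(config.backbone_variant, seed=config.seed)
    params = backbone.parameters()
    opt = Adam(params, lr=config.initial_lr, l2=config.l2_alpha)
    handle = ModelHandle(backbone, config)
    n = len(bags)
    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(epoch, config)
        order = rng.permutation(n)
        losses = []
        correct = 0
        backbone.train(True)
        for start in range(0, n, config.bag_batch_size):
            batch = [bags[i] for i in order[start:start + config.bag_batch_size]]
            backbone.zero_grad()
            ces = []
            for bag in batch:
                _, _, act, prob = _bag_forward(backbone, bag, config)
                ces.append(ops.binary_cross_entropy(prob, float(bag.label),
                                                    LOG_CLIP_DELTA))
                correct += int((float(act.data) > config.threshold) == (bag.label == 0))
            total = ces[0]
            for c in ces[1:]:
                total = ops.add(total, c)
            total = ops.scale(total, 1.0 / len(ces))
            total.backward()
            opt.step()
            l2 = config.l2_alpha * sum(float((p.data ** 2).sum()) for p in params)
            losses.append(total.item() + l2)
        handle.history["loss"].append(float(np.mean(losses)))
        handle.history["accuracy"].append(correct / n)
    backbone.eval()
    return handle


def predict_slide(model: ModelHandle, bag: Bag) -> BagScore:
    """Score every tile of one slide and derive the bag-level quantities.

    Deterministic: the backbone runs in inference mode (running batch-norm
    statistics, no augmentation).
    """
    if len(bag) < 1:
        raise ValueError("empty bag")
    config = model.config
    model.backbone.eval()
    with no_grad():
        scores = model.backbone(Tensor(bag.tiles)).data.astype(np.float64)
    agg = aggregate_scores(scores, config.aggregation_exponent,
                           power_mean=config.power_mean)
    activated, cls = classify_bag(agg, config.threshold)
    prob = transform_probability(activated, config.threshold)
    return BagScore(slide_id=bag.slide_id, tile_scores=scores, aggregate=agg,
                    activated=activated, prob=prob, predicted_class=cls)


def rank_tiles(model: ModelHandle, bags: list[Bag], k_per_class: int):
    """Retrieve the k highest- and k lowest-scoring tiles across a cohort.

    Returns ``(high, low)``: lists of dicts with slide id, tile index and
    score, sorted by score (descending for high, ascending for low).  Ties
    are broken by (slide_id, tile index) for determinism.
    """
    rows = []
    for bag in bags:
        sc = predict_slide(model, bag)
        for i, s in enumerate(sc.tile_scores):
            rows.append({"slide_id": bag.slide_id, "tile_index": i,
                         "score": float(s),
                         **{k: v[i] for k, v in bag.meta.items()
                            if isinstance(v, (list, np.ndarray)) and len(v) == len(bag)}})
    if len(rows) < 2 * k_per_class:
        raise ValueError("not enough tiles to rank")
    high = sorted(rows, key=lambda r: (-r["score"], r["slide_id"], r["tile_index"]))
    low = sorted(rows, key=lambda r: (r["score"], r["slide_id"], r["tile_index"]))
    return high[:k_per_class], low[:k_per_class]
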