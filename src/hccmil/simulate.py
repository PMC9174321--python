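"""Synthetic histology simulation: nuclei-bearing tiles with ground-truth
masks, class-labelled slide bags, and proportional-hazards survival cohorts.

The tile generator encodes four histological axes along which high- and
low-risk tissue differ: nuclear size (cytological atypia), nuclear darkness
(hyperchromasia), fibrous stroma banding, and immune-cell density (small
round dark dots, enriched in low-risk tissue).  Nuclei are ellipses over an
eosin-like textured background; "stroma" is low-frequency oriented banding.
Every generated tile records whether it is a signal tile and every simulated
subject records its true linear predictor, so downstream statistics can be
tested against known ground truth.

All generators are pure functions of their configuration including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mil import Bag, assemble_four_channel

__all__ = [
    "NucleusSpec", "SlideSimConfig", "SurvivalSimConfig", "CalibrationError",
    "generate_nuclei_tile", "generate_bag", "generate_cohort_bags",
    "generate_survival_cohort", "write_bag_dataset", "write_cohort_csv",
]


class CalibrationError(RuntimeError):
    """Raised when the censoring calibration cannot reach its target."""


# ---------------------------------------------------------------------------
# configuration and per-nucleus record
# ---------------------------------------------------------------------------

@dataclass
class NucleusSpec:
    """Geometry and staining of one simulated nucleus.

    ``intensity`` is the chromasia level in [0, 255]: 0 renders white,
    255 renders the deepest hematoxylin purple (darkest).
    """

    center: tuple[float, float]        # (x, y) pixels
    radii: tuple[float, float]         # (major, minor) pixels
    angle: float                       # radians
    intensity: float                   # 0-255 chromasia
    type: str                          # "tumor_nucleus" | "immune_cell"

    def __post_init__(self):
        if self.radii[0] <= 0 or self.radii[1] <= 0:
            raise ValueError("nucleus radii must be positive")
        if not 0 <= self.intensity <= 255:
            raise ValueError("intensity must lie in [0, 255]")
        if self.type not in ("tumor_nucleus", "immune_cell"):
            raise ValueError(f"unknown nucleus type {self.type!r}")

    @property
    def area(self) -> float:
        return math.pi * self.radii[0] * self.radii[1]


@dataclass
class SlideSimConfig:
    """Study conditions for one simulated slide (bag of tiles)."""

    n_tiles: int = 16
    tile_size: int = 64
    signal_fraction: float = 0.5
    stroma_probability: float = 0.6
    immune_density: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.tile_size < 32:
            raise ValueError("tile_size must be >= 32")
        if not 0.0 <= self.stroma_probability <= 1.0:
            raise ValueError("stroma_probability must lie in [0, 1]")
        if self.immune_density < 0:
            raise ValueError("immune_density must be non-negative")


@dataclass
class SurvivalSimConfig:
    """Weibull proportional-hazards cohort with a binary marker and an
    ordered stage factor; censoring uniform on (0, c_max) with c_max
    calibrated by bisection to hit the target censoring fraction."""

    n_subjects: int = 200
    log_hazard_ratios: dict = field(
        default_factory=lambda: {"marker": math.log(2.0), "stage": 0.3})
    baseline_shape: float = 1.5
    baseline_scale: float = 24.0       # months
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")


# ---------------------------------------------------------------------------
# tile rendering
# ---------------------------------------------------------------------------

# deep hematoxylin purple reached at chromasia 255
_HEMATOXYLIN_RGB = np.array([70.0, 50.0, 135.0])
# eosin-like background
_EOSIN_RGB = np.array([238.0, 188.0, 212.0])
_STROMA_RGB = np.array([222.0, 155.0, 185.0])


def _sample_nuclei(rng: np.random.Generator, config: SlideSimConfig,
                   is_signal: bool, n_nuclei: int | None) -> list[NucleusSpec]:
    size = config.tile_size
    scale = size / 64.0                      # radii scale with tile size
    area_scale = scale ** 2
    specs: list[NucleusSpec] = []

    if n_nuclei is None:
        n_tumor = rng.poisson(11 * area_scale)
    else:
        n_tumor = n_nuclei
    for _ in range(n_tumor):
        if is_signal:
            major = rng.uniform(5.0, 9.0) * scale       # atypia: large
            minor = major * rng.uniform(0.45, 0.75)     # eccentric
            intensity = rng.uniform(170.0, 240.0)       # hyperchromatic
        else:
            major = rng.uniform(2.8, 4.6) * scale       # small
            minor = major * rng.uniform(0.82, 1.0)      # round
            intensity = rng.uniform(90.0, 150.0)        # pale
        margin = major + 1
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        specs.append(NucleusSpec((cx, cy), (major, minor),
                                 rng.uniform(0, math.pi), intensity,
                                 "tumor_nucleus"))

    # immune infiltration marks low-risk tissue; signal tiles are depleted
    mean_immune = config.immune_density * area_scale * (0.15 if is_signal else 1.0)
    n_immune = rng.poisson(mean_immune) if n_nuclei is None else 0
    for _ in range(n_immune):
        r = rng.uniform(1.4, 2.4) * scale
        cx = rng.uniform(r + 1, size - r - 1)
        cy = rng.uniform(r + 1, size - r - 1)
        specs.append(NucleusSpec((cx, cy), (r, r * rng.uniform(0.9, 1.0)),
                                 rng.uniform(0, math.pi), rng.uniform(200.0, 245.0),
                                 "immune_cell"))
    return specs


def _render(specs: list[NucleusSpec], config: SlideSimConfig,
            rng: np.random.Generator, with_stroma: bool):
    size = config.tile_size
    img = np.tile(_EOSIN_RGB, (size, size, 1))
    if with_stroma:
        # low-frequency oriented fibrous banding
        theta = rng.uniform(0, math.pi)
        freq = rng.uniform(0.25, 0.5)
        phase = rng.uniform(0, 2 * math.pi)
        yy, xx = np.mgrid[0:size, 0:size]
        band = 0.5 * (1 + np.sin(freq * (xx * math.cos(theta)
                                         + yy * math.sin(theta)) + phase))
        band = band[..., None] ** 3
        img = img * (1 - 0.7 * band) + _STROMA_RGB * 0.7 * band

    mask = np.zeros((size, size), dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    for sp in specs:
        a, b = sp.radii
        ca, sa = math.cos(sp.angle), math.sin(sp.angle)
        dx, dy = xx - sp.center[0], yy - sp.center[1]
        u = (dx * ca + dy * sa) / a
        v = (-dx * sa + dy * ca) / b
        inside = u * u + v * v <= 1.0
        mask[inside] = 1
        frac = sp.intensity / 255.0
        color = 255.0 - (255.0 - _HEMATOXYLIN_RGB) * frac
        img[inside] = img[inside] * (1 - 0.9 * frac) + color * 0.9 * frac

    img += rng.normal(0.0, 6.0, size=img.shape)       # texture noise
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def generate_nuclei_tile(config: SlideSimConfig, risk_class: str,
                         is_signal: bool, seed: int,
                         n_nuclei: int | None = None):
    """Render one RGB tile with its binary nuclei mask.

    Signal tiles carry the high-risk morphology (large, dark, eccentric
    nuclei, possible stroma banding, depleted immune cells); non-signal
    tiles carry small round pale nuclei and immune-cell dots.  The mask is
    1 exactly on nucleus interiors (tumor nuclei and immune cells alike).

    Returns ``(tile uint8 HxWx3, mask uint8 HxW, list of NucleusSpec)``.
    """
    if risk_class not in ("high", "low"):
        raise ValueError("risk_class must be 'high' or 'low'")
    if is_signal and risk_class != "high":
        raise ValueError("signal tiles only occur in high-risk slides")
    rng = np.random.default_rng(seed)
    specs = _sample_nuclei(rng, config, is_signal, n_nuclei)
    with_stroma = bool(is_signal and rng.uniform() < config.stroma_probability)
    img, mask = _render(specs, config, rng, with_stroma)
    return img, mask, specs


# ---------------------------------------------------------------------------
# bags
# ---------------------------------------------------------------------------

def generate_bag(config: SlideSimConfig, risk_class: str,
                 slide_id: str | None = None) -> Bag:
    """Generate one slide bag.

    For a high-risk slide, ceil(signal_fraction * n_tiles) tiles are signal
    tiles; low-risk slides contain none.  The bag label follows the package
    convention y = 1 for low risk (good outcome).  The ground-truth nuclei
    mask serves as the fourth (heatmap) channel; the pipeline substitutes a
    trained U-net's soft output.  Provenance lives in ``bag.meta``:
    ``is_signal`` flags, raw RGB tiles and masks.
    """
    if risk_class not in ("high", "low"):
        raise ValueError("risk_class must be 'high' or 'low'")
    n_signal = math.ceil(config.signal_fraction * config.n_tiles) \
        if risk_class == "high" else 0
    rng = np.random.default_rng(config.seed)
    tiles, rgbs, masks, flags, spec_lists = [], [], [], [], []
    for i in range(config.n_tiles):
        is_signal = i < n_signal
        tile_seed = int(rng.integers(0, 2 ** 31 - 1))
        img, mask, specs = generate_nuclei_tile(
            config, risk_class if is_signal else risk_class, is_signal, tile_seed)
        tiles.append(assemble_four_channel(img, mask.astype(np.float32)))
        rgbs.append(img)
        masks.append(mask)
        flags.append(is_signal)
        spec_lists.append(specs)
    sid = slide_id or f"slide-{config.seed:08d}-{risk_class}"
    return Bag(slide_id=sid, tiles=np.stack(tiles),
               label=0 if risk_class == "high" else 1,
               meta={"is_signal": np.array(flags), "rgb": np.stack(rgbs),
                     "mask": np.stack(masks), "nuclei": spec_lists,
                     "risk_class": risk_class})


def generate_cohort_bags(n_per_class: int, config: SlideSimConfig,
                         seed: int | None = None) -> list[Bag]:
    """Generate a balanced cohort of high- and low-risk bags.

    Per-bag seeds are spawned deterministically from ``seed`` (defaults to
    ``config.seed``).
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base)
    bags = []
    for i in range(n_per_class):
        for risk in ("high", "low"):
            cfg = SlideSimConfig(**{**config.__dict__,
                                    "seed": int(rng.integers(0, 2 ** 31 - 1))})
            bags.append(generate_bag(cfg, risk, slide_id=f"slide-{risk}-{i:04d}"))
    return bags


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def _calibrate_cmax(times: np.ndarray, target: float) -> float:
    """Solve for c_max such that mean_i P(U(0,c_max) < T_i) == target."""

    def frac(cmax):
        return float(np.minimum(times / cmax, 1.0).mean())

    lo, hi = 1e-6, float(times.max()) * 1e4
    if frac(hi) > target:       # even huge horizons censor too much (degenerate)
        raise CalibrationError(
            f"cannot reach censoring rate {target}: residual {frac(hi):.3f} at c_max={hi:.3g}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    cmax = 0.5 * (lo + hi)
    if abs(frac(cmax) - target) > 0.02:
        raise CalibrationError(
            f"censoring calibration residual {abs(frac(cmax) - target):.3f} "
            f"exceeds 0.02 at c_max={cmax:.3g}")
    return cmax


def generate_survival_cohort(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate a right-censored cohort under a Weibull PH model.

    Event times follow S(t | x) = exp(-(t/scale)^shape * exp(lp)) with
    lp = sum_j beta_j x_j; covariates are a binary ``marker`` (Bernoulli 0.5)
    and an ordered ``stage`` in {1, 2, 3}.  Censoring times are uniform on
    (0, c_max) with c_max solved by bisection so the expected censoring
    fraction matches the target.  The true linear predictor is recorded per
    subject.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    marker = rng.integers(0, 2, size=n)
    stage = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
    betas = config.log_hazard_ratios
    lp = (betas.get("marker", 0.0) * marker
          + betas.get("stage", 0.0) * (stage - 1))
    u = rng.uniform(size=n)
    times = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)
    times = np.maximum(times, 1e-6)
    if config.censoring_rate == 0.0:
        observed = times
        event = np.ones(n, dtype=int)
    else:
        cmax = _calibrate_cmax(times, config.censoring_rate)
        cens = rng.uniform(0.0, cmax, size=n)
        event = (times <= cens).astype(int)
        observed = np.minimum(times, cens)
    return pd.DataFrame({
        "id": [f"subj-{i:05d}" for i in range(n)],
        "time": observed,
        "event": event,
        "marker": marker,
        "stage": stage,
        "true_linear_predictor": lp,
    })


# ---------------------------------------------------------------------------
# on-disk dataset writers
# ---------------------------------------------------------------------------

def write_bag_dataset(bags: list[Bag], out_dir) -> pd.DataFrame:
    """Write tiles/masks as PNG plus a manifest CSV.

    Manifest columns: slide_id, tile_path, mask_path, x, y, is_signal,
    bag_label.  Simulated tiles have no source-slide offset, so x/y record
    the tile index grid position.
    """
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    (out / "tiles").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for bag in bags:
        for i in range(len(bag)):
            tp = out / "tiles" / f"{bag.slide_id}_{i:04d}.png"
            mp = out / "masks" / f"{bag.slide_id}_{i:04d}.png"
            Image.fromarray(bag.meta["rgb"][i]).save(tp)
            Image.fromarray(bag.meta["mask"][i] * 255).save(mp)
            rows.append({"slide_id": bag.slide_id, "tile_path": str(tp),
                         "mask_path": str(mp), "x": i, "y": 0,
                         "is_signal": bool(bag.meta["is_signal"][i]),
                         "bag_label": bag.label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
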