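"""Tile extraction and resizing.

Large stained images are cut into fixed-size square tiles on a regular
grid; tiles that are mostly background (near-white) are dropped.  The
canonical working geometry is 512 px tiles at 0.25 µm/px, bilinearly
resized to 224 px for the classifier; any sizes are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["TileRecord", "extract_tiles", "resize_tile", "tissue_fraction",
           "WHITENESS_CUTOFF"]

#: a pixel is background when its mean RGB exceeds this (standard WSI practice)
WHITENESS_CUTOFF = 220.0


@dataclass
class TileRecord:
    """One square RGB tile with its provenance.

    ``origin`` is the (x, y) pixel offset of the tile's top-left corner in
    the source image, 0-based, half-open intervals; ``mpp`` is microns per
    pixel.
    """

    pixels: np.ndarray
    slide_id: str
    origin: tuple[int, int]
    mpp: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("tile pixels must be a square HxWx3 array")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("origin must be non-negative")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def tissue_fraction(pixels: np.ndarray,
                    whiteness_cutoff: float = WHITENESS_CUTOFF) -> float:
    """Fraction of pixels that are tissue (mean RGB below the cutoff)."""
    lum = np.asarray(pixels, dtype=np.float32).mean(axis=2)
    return float((lum < whiteness_cutoff).mean())


def extract_tiles(image: np.ndarray, slide_id: str = "slide", *,
                  tile_size: int = 512, stride: int | None = None,
                  tissue_threshold: float = 0.25, mpp: float = 0.25,
                  whiteness_cutoff: float = WHITENESS_CUTOFF) -> list[TileRecord]:
    """Grid-tile an RGB image, keeping tiles with enough tissue.

    A tile is kept iff its non-background pixel fraction is at least
    ``tissue_threshold``.  With ``stride == tile_size`` (default) the grid is
    exhaustive and non-overlapping: floor(W/ts) * floor(H/ts) candidate
    tiles.  An image smaller than ``tile_size`` yields an empty list with a
    warning rather than an error.
    """
    if not 0.0 <= tissue_threshold <= 1.0:
        raise ValueError("tissue_threshold must lie in [0, 1]")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB HxWx3 image")
    stride = tile_size if stride is None else stride
    H, W = image.shape[:2]
    if H < tile_size or W < tile_size:
        warnings.warn(f"image {W}x{H} smaller than tile_size {tile_size}; "
                      "no tiles extracted", stacklevel=2)
        return []
    out = []
    for y in range(0, H - tile_size + 1, stride):
        for x in range(0, W - tile_size + 1, stride):
            px = image[y:y + tile_size, x:x + tile_size]
            if tissue_fraction(px, whiteness_cutoff) >= tissue_threshold:
                out.append(TileRecord(px.copy(), slide_id, (x, y), mpp))
    return out


def resize_tile(tile: TileRecord, target: int) -> TileRecord:
    """Bilinearly resample a tile to ``target`` px, rescaling its mpp.

    A 512 px tile at 0.25 µm/px resized to 224 px has
    mpp = 0.25 * 512/224 ≈ 0.5714 µm/px.
    """
    if not isinstance(target, (int, np.integer)) or target < 8:
        raise ValueError("target size must be an integer >= 8")
    if target == tile.size:
        return TileRecord(tile.pixels.copy(), tile.slide_id, tile.origin, tile.mpp)
    src = tile.pixels
    out = _sk_resize(src.astype(np.float64), (target, target, src.shape[2]),
                     order=1, mode="edge", anti_aliasing=target < tile.size,
                     preserve_range=True)
    if np.issubdtype(src.dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(src.dtype)
    else:
        out = out.astype(src.dtype)
    return TileRecord(out, tile.slide_id, tile.origin,
                      tile.mpp * tile.size / target)
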