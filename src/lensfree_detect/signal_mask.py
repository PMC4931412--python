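"""Adaptive local thresholding of a frame into a binary signal mask.

Lens-free frames have a non-uniform background that varies across the
large field of view and between sample types, so a single global
threshold mislabels whole regions.  Instead the frame is tiled into
small windows; a window only contributes signal pixels when its local
contrast (max − min) exceeds a floor, and the local threshold is the
midpoint (max + min) / 2.  Diffraction signals sit below the local
background (the central lobe and dark annulus), so the default polarity
marks pixels *below* the threshold.

A plain Otsu global threshold is provided as the baseline the adaptive
method is designed to beat on gradient-lit frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

from .imaging_io import GrayImage

Polarity = Literal["dark", "bright", "minority"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of the patch-wise adaptive threshold.

    Attributes
    ----------
    window
        Side of the square tiling window in px (default 10, matching the
        ~10–15 px footprint of a diffraction pattern's central structure).
    contrast_min
        Local max − min must strictly exceed this many gray levels for a
        window to contribute signal pixels (default 30).
    polarity
        Which side of the midpoint threshold counts as signal: ``dark``
        (value < T, the default), ``bright`` (value > T), or ``minority``
        (the smaller of the two classes; ties go dark).
    stride
        Step between windows; defaults to ``window`` (non-overlapping
        tiling). Exposed for experimentation only.
    """

    window: int = 10
    contrast_min: int = 30
    polarity: Polarity = "dark"
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.contrast_min < 0:
            raise ValueError("contrast_min must be >= 0")
        if self.polarity not in ("dark", "bright", "minority"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")


def _mark_patch(patch: np.ndarray, contrast_min: int, polarity: Polarity) -> np.ndarray:
    """Apply the midpoint-threshold rule to one window; returns its bits."""
    lo = int(patch.min())
    hi = int(patch.max())
    if hi - lo <= contrast_min:
        return np.zeros(patch.shape, dtype=bool)
    t = (hi + lo) / 2.0  # may be fractional; compared exactly
    below = patch < t
    if polarity == "dark":
        return below
    above = patch > t
    if polarity == "bright":
        return above
    # minority: the smaller class; ties go dark
    return below if below.sum() <= above.sum() else above


def local_threshold_mask(img: GrayImage, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """Patch-wise adaptive threshold; returns a boolean mask of the
    frame's probable signal pixels (same shape as the image).

    Right/bottom remainder windows are processed at their reduced size so
    no frame area is blind.
    """
    cfg = cfg or ThresholdConfig()
    px = img.pixels
    h, w = px.shape
    win = cfg.window
    stride = cfg.stride if cfg.stride is not None else cfg.window
    mask = np.zeros((h, w), dtype=bool)

    if stride == win and h % win == 0 and w % win == 0:
        return _tiled_fast(px, cfg)

    for r0 in range(0, h, stride):
        for c0 in range(0, w, stride):
            patch = px[r0:r0 + win, c0:c0 + win]
            mask[r0:r0 + win, c0:c0 + win] |= _mark_patch(patch, cfg.contrast_min, cfg.polarity)
    return mask


def _tiled_fast(px: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Vectorised non-overlapping tiling for exactly divisible frames."""
    h, w = px.shape
    win = cfg.window
    blocks = px.reshape(h // win, win, w // win, win).swapaxes(1, 2)  # (br, bc, win, win)
    lo = blocks.min(axis=(2, 3)).astype(np.int64)
    hi = blocks.max(axis=(2, 3)).astype(np.int64)
    active = (hi - lo) > cfg.contrast_min
    t = (hi + lo) / 2.0
    below = blocks < t[:, :, None, None]
    if cfg.polarity == "dark":
        bits = below
    elif cfg.polarity == "bright":
        bits = blocks > t[:, :, None, None]
    else:
        above = blocks > t[:, :, None, None]
        n_below = below.sum(axis=(2, 3))
        n_above = above.sum(axis=(2, 3))
        pick_dark = (n_below <= n_above)[:, :, None, None]
        bits = np.where(pick_dark, below, above)
    bits &= active[:, :, None, None]
    return bits.swapaxes(1, 2).reshape(h, w)


def global_threshold_mask(img: GrayImage) -> np.ndarray:
    """Single Otsu threshold over the whole frame (dark pixels set).

    This is the baseline the adaptive method is compared against; it has
    no defence against background gradients.  Constant images yield an
    empty mask (no valid bimodal split).
    """
    px = img.pixels
    if px.min() == px.max():
        return np.zeros(px.shape, dtype=bool)
    t = threshold_otsu(px)
    return px <= t  # threshold_otsu convention: foreground is strictly above t


def mask_to_image(mask: np.ndarray, pixel_pitch: float = 2.2) -> GrayImage:
    """Render a boolean mask as a 0/255 frame for visual inspection."""
    return GrayImage((mask.astype(np.uint8) * 255), pixel_pitch=pixel_pitch)
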