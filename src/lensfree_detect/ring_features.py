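"""Diffraction-parameter extraction and the circularity filter.

Each candidate center is characterised by four parameters measured on
the horizontal and vertical intensity profiles through its midpoint:

* **CMV** — central maxima value, the gray level at the midpoint pixel;
* **WCX** — width of the central maxima: the contiguous run of pixels
  through the midpoint whose values stay within ``cmv_tol`` of the CMV;
* **WCN** — width of the central minima: the dark-annulus lobe adjacent
  to the central run on each side (pixels strictly below the CMV),
  averaged over the two sides;
* **PPD** — peak-to-peak distance: the pixel distance between the two
  first-order bright peaks flanking the center, measured on a smoothed
  profile.  PPD carries the size information (size ≈ 0.28 × PPD µm).

True diffraction patterns are circular, so the vertical/horizontal
aspect ratios of WCX and WCN are both required to be near 1; elongated
streaks and other non-circular noise fail this filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .imaging_io import GrayImage

Axis = str  # "h" (along the row) or "v" (along the column)


@dataclass(frozen=True)
class FeatureConfig:
    """Tolerances of the feature measurements.

    Attributes
    ----------
    cmv_tol
        Gray-level tolerance quantifying "similar to the CMV"
        (default 10, about a third of the 30-unit contrast floor).
    scan_max
        Outward scan limit per side, in px from the midpoint
        (default 60; first-order peaks of the largest targets sit
        within ~55 px).
    smooth
        Width of the moving-average applied before peak finding
        (odd, default 3); single-pixel noise spikes must not register
        as first-order peaks.
    max_aspect
        Circularity tolerance: max/min of the vertical/horizontal width
        pair, for both WCX and WCN (default 1.5).
    denoise_sigma
        Gaussian blur applied to the frame before the width/peak
        measurements (default 1.0 px; 0 disables).  The integer widths
        feeding the aspect-ratio filter are only a few pixels, so
        single-pixel noise at a run boundary would otherwise flip the
        circularity verdict; an isotropic blur stabilises both axes
        identically and leaves aspect ratios unbiased.
    peak_prominence
        Minimum topographic prominence (gray levels) for a smoothed
        local maximum to count as the first-order peak (default 5);
        rejects noise wiggles and the rings of distant neighbours.
    """

    cmv_tol: int = 10
    scan_max: int = 60
    smooth: int = 3
    max_aspect: float = 1.5
    denoise_sigma: float = 1.0
    peak_prominence: float = 5.0

    def __post_init__(self) -> None:
        if self.cmv_tol < 0:
            raise ValueError("cmv_tol must be >= 0")
        if self.scan_max <= 0:
            raise ValueError("scan_max must be > 0")
        if self.smooth < 1 or self.smooth % 2 == 0:
            raise ValueError("smooth must be odd and >= 1")
        if self.max_aspect < 1:
            raise ValueError("max_aspect must be >= 1")
        if self.denoise_sigma < 0:
            raise ValueError("denoise_sigma must be >= 0")
        if self.peak_prominence < 0:
            raise ValueError("peak_prominence must be >= 0")


@dataclass(frozen=True)
class RingFeatures:
    """The four diffraction parameters of one candidate, per axis."""

    cmv: int
    wcx_h: int
    wcx_v: int
    wcn_h: int
    wcn_v: int
    ppd_h: Optional[int]
    ppd_v: Optional[int]
    ppd: Optional[float]


def _profile(img: GrayImage, midpoint: tuple[int, int], axis: Axis) -> tuple[np.ndarray, int]:
    """The intensity profile through ``midpoint`` and its index on it."""
    r, c = midpoint
    if not img.in_bounds(midpoint):
        raise ValueError(f"midpoint {midpoint} outside {img.height}x{img.width} frame")
    if axis == "h":
        return img.pixels[r, :].astype(np.int64), c
    if axis == "v":
        return img.pixels[:, c].astype(np.int64), r
    raise ValueError(f"axis must be 'h' or 'v', got {axis!r}")


def extract_cmv(img: GrayImage, midpoint: tuple[int, int]) -> int:
    """Gray level at the midpoint pixel (the central maxima value)."""
    if not img.in_bounds(midpoint):
        raise ValueError(f"midpoint {midpoint} outside {img.height}x{img.width} frame")
    return int(img.pixels[midpoint])


def _expand_run(ok: np.ndarray, pos: int) -> tuple[int, int]:
    """Bounds [lo, hi] of the contiguous True-run containing ``pos``."""
    n = len(ok)
    lo = pos
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = pos
    while hi < n - 1 and ok[hi + 1]:
        hi += 1
    return lo, hi


def _central_run(profile: np.ndarray, pos: int, cmv: int, tol: int) -> tuple[int, int]:
    """Bounds [lo, hi] of the maximal near-CMV run containing ``pos``."""
    return _expand_run(np.abs(profile - cmv) <= tol, pos)


def _robust_cmv(img: GrayImage, midpoint: tuple[int, int]) -> int:
    """CMV estimated as the median of the 3×3 neighbourhood.

    The central lobe is several pixels wide, so the median over the
    immediate neighbourhood is still the central maxima value but does
    not hinge on a single noisy pixel.
    """
    r, c = midpoint
    patch = img.pixels[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
    return int(np.median(patch))


def central_width(img: GrayImage, midpoint: tuple[int, int], axis: Axis,
                  cfg: FeatureConfig | None = None,
                  cmv: int | None = None) -> int:
    """WCX along one axis: length of the contiguous run through the
    midpoint where ``|value − CMV| <= cmv_tol``.

    ``cmv`` defaults to the midpoint pixel value; a caller may supply a
    robust estimate instead (see :func:`extract_features`).
    """
    cfg = cfg or FeatureConfig()
    profile, pos = _profile(img, midpoint, axis)
    if cmv is None:
        cmv = int(profile[pos])
    lo, hi = _central_run(profile, pos, cmv, cfg.cmv_tol)
    return hi - lo + 1


def minima_width(img: GrayImage, midpoint: tuple[int, int], axis: Axis,
                 cfg: FeatureConfig | None = None,
                 cmv: int | None = None) -> int:
    """WCN along one axis: length of the dark-annulus lobe (pixels
    strictly below the CMV) immediately outside the central run,
    averaged over the two sides (rounded half away from zero).

    The dark-run cut is the CMV itself, not ``CMV − cmv_tol``: the
    annulus floor sits well below the CMV, so this keeps the measurement
    stable against single-pixel noise at the run boundary.
    """
    cfg = cfg or FeatureConfig()
    profile, pos = _profile(img, midpoint, axis)
    if cmv is None:
        cmv = int(profile[pos])
    lo, hi = _central_run(profile, pos, cmv, cfg.cmv_tol)
    dark = profile < cmv
    left = _lobe_length(dark, lo - 1, -1)
    right = _lobe_length(dark, hi + 1, +1)
    return int(np.floor((left + right) / 2.0 + 0.5))


def _lobe_length(dark: np.ndarray, start: int, step: int) -> int:
    """Length of the dark lobe beginning at ``start`` going ``step``-ward."""
    n = len(dark)
    if not 0 <= start < n or not dark[start]:
        return 0
    lo, hi = _expand_run(dark, start)
    return (hi - start + 1) if step > 0 else (start - lo + 1)


def _side_peak(smoothed: np.ndarray, start: int, stop: int, step: int,
               prominence: float) -> Optional[int]:
    """Position of the first-order peak on one side of the center.

    ``start`` is the first index outside the central run; the scan runs
    outward to ``stop`` (inclusive) in direction ``step``.  The profile
    descends into the annulus minimum and rises to the first-order
    bright ring, so the peak is the first local maximum (outward) with
    at least ``prominence`` gray levels of topographic prominence —
    minor noise wiggles and, crucially, the rings of more distant
    neighbouring patterns are ignored.  Returns None when no such peak
    exists in the segment.
    """
    from scipy.signal import find_peaks

    idx = np.arange(start, stop + step, step)
    if len(idx) < 3:
        return None
    seg = smoothed[idx]
    peaks, _ = find_peaks(seg, prominence=prominence)
    if len(peaks) == 0:
        return None
    return int(idx[peaks[0]])


def find_ppd(img: GrayImage, midpoint: tuple[int, int], axis: Axis,
             cfg: FeatureConfig | None = None,
             cmv: int | None = None) -> Optional[int]:
    """Peak-to-peak distance along one axis, or None.

    The profile is smoothed with a ``smooth``-wide moving average, then
    each side is scanned outward from the central run up to ``scan_max``
    px from the midpoint: the annulus minimum is located first and the
    first-order bright peak beyond it.  The PPD is the distance between
    the left and right peak positions.  Returns None (absent) when a
    peak is missing or the scan would leave the frame.
    """
    cfg = cfg or FeatureConfig()
    profile, pos = _profile(img, midpoint, axis)
    n = len(profile)
    if pos - cfg.scan_max < 0 or pos + cfg.scan_max > n - 1:
        return None  # scan would hit the frame border
    if cmv is None:
        cmv = int(profile[pos])
    lo, hi = _central_run(profile, pos, cmv, cfg.cmv_tol)
    if lo - 1 < pos - cfg.scan_max or hi + 1 > pos + cfg.scan_max:
        return None  # central run fills the scan range (flat profile)
    smoothed = uniform_filter1d(profile.astype(np.float64), size=cfg.smooth,
                                mode="nearest")
    left = _side_peak(smoothed, lo - 1, pos - cfg.scan_max, -1, cfg.peak_prominence)
    right = _side_peak(smoothed, hi + 1, pos + cfg.scan_max, +1, cfg.peak_prominence)
    if left is None or right is None:
        return None
    return int(right - left)


def circularity_ok(f: RingFeatures, cfg: FeatureConfig | None = None) -> bool:
    """Whether the candidate passes the circularity filter.

    Both the WCX and the WCN vertical/horizontal pairs must have
    max/min aspect ratio at most ``max_aspect``; a pair with exactly one
    zero width fails, a pair with both widths zero passes.
    """
    cfg = cfg or FeatureConfig()

    def pair_ok(a: int, b: int) -> bool:
        if a == 0 and b == 0:
            return True
        if a == 0 or b == 0:
            return False
        return max(a, b) / min(a, b) <= cfg.max_aspect

    return pair_ok(f.wcx_h, f.wcx_v) and pair_ok(f.wcn_h, f.wcn_v)


def denoise_for_features(img: GrayImage, sigma: float) -> GrayImage:
    """Gaussian-blurred copy of a frame for stable feature measurement."""
    from scipy.ndimage import gaussian_filter

    blurred = gaussian_filter(img.pixels.astype(np.float64), sigma, mode="nearest")
    return GrayImage(np.clip(np.rint(blurred), 0, 255).astype(np.uint8),
                     pixel_pitch=img.pixel_pitch)


def extract_features(img: GrayImage, midpoint: tuple[int, int],
                     cfg: FeatureConfig | None = None,
                     pre_denoised: bool = False) -> RingFeatures:
    """Measure all four diffraction parameters at a candidate midpoint.

    The CMV used for the run measurements is the 3×3-median estimate
    (identical to the midpoint pixel on noise-free frames); all widths
    and peak positions derive from it consistently.  When
    ``denoise_sigma`` > 0 the measurements run on a Gaussian-blurred
    copy of the frame (see :func:`denoise_for_features`); callers
    processing many candidates should pre-blur once and pass
    ``pre_denoised=True``.
    """
    cfg = cfg or FeatureConfig()
    if cfg.denoise_sigma > 0 and not pre_denoised:
        img = denoise_for_features(img, cfg.denoise_sigma)
    cmv = _robust_cmv(img, midpoint)
    ppd_h = find_ppd(img, midpoint, "h", cfg, cmv=cmv)
    ppd_v = find_ppd(img, midpoint, "v", cfg, cmv=cmv)
    available = [p for p in (ppd_h, ppd_v) if p is not None]
    ppd = float(np.mean(available)) if available else None
    return RingFeatures(
        cmv=cmv,
        wcx_h=central_width(img, midpoint, "h", cfg, cmv=cmv),
        wcx_v=central_width(img, midpoint, "v", cfg, cmv=cmv),
        wcn_h=minima_width(img, midpoint, "h", cfg, cmv=cmv),
        wcn_v=minima_width(img, midpoint, "v", cfg, cmv=cmv),
        ppd_h=ppd_h,
        ppd_v=ppd_v,
        ppd=ppd,
    )
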