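"""Counting, sizing and concentration estimates from accepted detections.

The physical size of a micro-object is linearly related to the
peak-to-peak distance of its diffraction pattern; with the fixed
LED–sample–sensor geometry and 2.2 µm pixel pitch of the reference rig
the calibration is ``Y [µm] = 0.28 · X [px]``.  The coefficient is
exposed in :class:`QuantifyConfig` because any other rig geometry needs
its own calibration.

Concentration uses a plain geometric chamber model: accepted count per
(frame area × chamber depth), where 1 mm³ = 1 µL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .imaging_io import DetectionRecord, GrayImage

#: Default µm-per-px(PPD) calibration coefficient of the reference rig.
SIZE_COEFF_UM_PER_PX = 0.28


@dataclass(frozen=True)
class QuantifyConfig:
    size_coeff: float = SIZE_COEFF_UM_PER_PX  # µm per px of PPD
    chamber_depth_mm: Optional[float] = 0.1   # C-Chip depth; None disables concentration
    bin_width_um: float = 2.0

    def __post_init__(self) -> None:
        if not self.size_coeff > 0:
            raise ValueError("size_coeff must be > 0")
        if self.chamber_depth_mm is not None and not self.chamber_depth_mm > 0:
            raise ValueError("chamber_depth_mm must be > 0")
        if not self.bin_width_um > 0:
            raise ValueError("bin_width_um must be > 0")


@dataclass
class QuantResult:
    total_candidates: int
    accepted_count: int
    sizes_um: list[float]
    histogram_edges_um: np.ndarray
    histogram_counts: np.ndarray
    concentration_per_ul: Optional[float]

    def to_dict(self) -> dict:
        return {
            "total_candidates": self.total_candidates,
            "accepted_count": self.accepted_count,
            "sizes_um": list(self.sizes_um),
            "histogram_edges_um": [float(e) for e in self.histogram_edges_um],
            "histogram_counts": [int(c) for c in self.histogram_counts],
            "concentration_per_ul": self.concentration_per_ul,
        }


def size_from_ppd(ppd: float, cfg: QuantifyConfig | None = None) -> float:
    """Convert a peak-to-peak distance (px) to a physical size (µm)."""
    cfg = cfg or QuantifyConfig()
    if ppd < 0:
        raise ValueError("ppd must be >= 0")
    return cfg.size_coeff * ppd


def quantify(records: Sequence[DetectionRecord], img: GrayImage,
             cfg: QuantifyConfig | None = None) -> QuantResult:
    """Counts, size histogram and (optionally) concentration for one frame.

    Sizes come from each accepted record's mean PPD.  The histogram uses
    fixed-width bins anchored at 0 µm.  Concentration is accepted count
    per chamber volume (frame area × depth), in objects/µL.
    """
    cfg = cfg or QuantifyConfig()
    accepted = [r for r in records if r.accepted]
    sizes = [size_from_ppd(r.features.ppd, cfg) for r in accepted]

    if sizes:
        n_bins = int(np.floor(max(sizes) / cfg.bin_width_um)) + 1
    else:
        n_bins = 1
    edges = np.arange(n_bins + 1) * cfg.bin_width_um
    counts, _ = np.histogram(sizes, bins=edges)

    concentration = None
    if cfg.chamber_depth_mm is not None:
        volume_ul = img.area_mm2 * cfg.chamber_depth_mm  # mm^3 == µL
        concentration = len(accepted) / volume_ul

    return QuantResult(
        total_candidates=len(records),
        accepted_count=len(accepted),
        sizes_um=sizes,
        histogram_edges_um=edges,
        histogram_counts=counts,
        concentration_per_ul=concentration,
    )
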