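"""Image and result I/O.

All coordinate and format conventions live here: pixel coordinates are
``(row, col)``, 0-based, origin at the top-left; distances are in pixel
units unless a name carries the ``_um`` suffix.  Frames are 8-bit
grayscale; the default pixel pitch of 2.2 µm matches a 5 MP CMOS sensor
with a 1920 × 2560 px active area (23.52 mm²).
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

# ITU-R BT.601 luma weights, used when a user supplies a colour scan.
_BT601 = np.array([0.299, 0.587, 0.114])

DEFAULT_PIXEL_PITCH_UM = 2.2


class RejectionReason(enum.Enum):
    """Why a candidate pattern was discarded (or kept)."""

    NONE = "none"
    NOT_CIRCULAR = "not_circular"
    PPD_NOT_FOUND = "ppd_not_found"
    EDGE_TRUNCATED = "edge_truncated"


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 8-bit frame with physical pixel-pitch metadata.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array indexed ``(row, col)``.
    pixel_pitch
        Physical size of one pixel in µm (default 2.2).
    """

    pixels: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_mm2(self) -> float:
        """Physical sensing area of the frame in mm²."""
        return self.height * self.width * (self.pixel_pitch * 1e-3) ** 2

    def in_bounds(self, point: tuple[int, int]) -> bool:
        r, c = point
        return 0 <= r < self.height and 0 <= c < self.width


@dataclass
class DetectionRecord:
    """One candidate diffraction pattern and its fate in the pipeline."""

    center: tuple[int, int]
    features: Optional["RingFeatures"] = None  # noqa: F821 - forward ref
    size_um: float = 0.0
    accepted: bool = False
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reason is not RejectionReason.NONE:
            raise ValueError("accepted records must carry rejection_reason 'none'")
        if self.accepted and not self.size_um > 0:
            raise ValueError("accepted records must have a positive size")


def read_image(path: str | Path, pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM) -> GrayImage:
    """Read a PNG/TIFF/BMP/JPEG frame as an 8-bit grayscale :class:`GrayImage`.

    Multi-channel inputs are collapsed to luminance with BT.601 weights;
    16-bit inputs are rescaled linearly onto [0, 255].
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt/unreadable
        raise IOError(f"cannot read image file {path}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64) @ _BT601
    else:
        arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit input
        arr = arr * (255.0 / 65535.0)
    arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return GrayImage(arr, pixel_pitch=pixel_pitch)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale frame (format from the file suffix)."""
    iio.imwrite(Path(path), img.pixels)


_CSV_HEADER = [
    "id", "row", "col", "cmv", "wcx_h", "wcx_v", "wcn_h", "wcn_v",
    "ppd_px", "size_um", "accepted", "rejection_reason",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_detections(records: Sequence[DetectionRecord], path: str | Path,
                     config_echo: Optional[dict] = None) -> None:
    """Write a detection report: CSV per record plus a JSON sibling summary.

    The CSV uses '.' decimals and UTF-8 regardless of locale.  The JSON
    summary (same stem, ``.json`` suffix) carries candidate/accepted/
    rejected totals and an echo of the configuration used.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for i, rec in enumerate(records):
                f = rec.features
                writer.writerow([
                    i, rec.center[0], rec.center[1],
                    _fmt(f.cmv if f else None),
                    _fmt(f.wcx_h if f else None), _fmt(f.wcx_v if f else None),
                    _fmt(f.wcn_h if f else None), _fmt(f.wcn_v if f else None),
                    _fmt(f.ppd if f else None),
                    _fmt(rec.size_um),
                    str(rec.accepted).lower(),
                    rec.rejection_reason.value,
                ])
    except OSError as exc:
        raise IOError(f"cannot write detections to {path}") from exc
    accepted = sum(1 for r in records if r.accepted)
    summary = {
        "total_candidates": len(records),
        "accepted_count": accepted,
        "rejected_count": len(records) - accepted,
        "config": config_echo or {},
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2), encoding="utf-8")


def read_detections(path: str | Path) -> list[DetectionRecord]:
    """Re-parse a detection CSV written by :func:`write_detections`."""
    from .ring_features import RingFeatures

    records: list[DetectionRecord] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            has_features = row["cmv"] != ""
            feats = None
            if has_features:
                feats = RingFeatures(
                    cmv=int(row["cmv"]),
                    wcx_h=int(row["wcx_h"]), wcx_v=int(row["wcx_v"]),
                    wcn_h=int(row["wcn_h"]), wcn_v=int(row["wcn_v"]),
                    ppd_h=None, ppd_v=None,
                    ppd=float(row["ppd_px"]) if row["ppd_px"] else None,
                )
            records.append(DetectionRecord(
                center=(int(row["row"]), int(row["col"])),
                features=feats,
                size_um=float(row["size_um"]) if row["size_um"] else 0.0,
                accepted=row["accepted"] == "true",
                rejection_reason=RejectionReason(row["rejection_reason"]),
            ))
    return records


def write_overlay(img: GrayImage, records: Sequence[DetectionRecord],
                  path: str | Path, mark_rejected: bool = False) -> None:
    """Write an RGB copy of ``img`` with a circle of radius PPD/2 at each
    accepted center (green).  Rejected centers get a small red cross when
    ``mark_rejected`` is set.  Pixels outside drawn markers are untouched.
    """
    from skimage.draw import circle_perimeter

    rgb = np.stack([img.pixels] * 3, axis=-1).astype(np.uint8)
    for rec in records:
        r, c = rec.center
        if rec.accepted and rec.features is not None and rec.features.ppd:
            radius = max(2, int(round(rec.features.ppd / 2)))
            rr, cc = circle_perimeter(r, c, radius, shape=rgb.shape[:2])
            rgb[rr, cc] = (0, 200, 0)
        elif mark_rejected and not rec.accepted:
            for dr in range(-2, 3):
                for rr, cc in ((r + dr, c), (r, c + dr)):
                    if 0 <= rr < img.height and 0 <= cc < img.width:
                        rgb[rr, cc] = (220, 0, 0)
    iio.imwrite(Path(path), rgb)
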