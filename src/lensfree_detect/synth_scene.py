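"""Synthetic lens-free frame renderer with exact ground truth.

Real diffraction patterns of micro-beads and cells share one empirical
shape: a central lobe somewhat darker than the background, a dark
annulus around it, and an outer first-order bright ring whose radius
grows with object size while the central widths stay nearly constant.
The renderer reproduces that shape phenomenologically — it is *not* a
physical (Fresnel) diffraction computation — because the detector only
assumes the center/annulus/ring structure.

The ground-truth link between object size and ring radius inverts the
sizing calibration: ``R = (size_um / 0.28) / 2`` px, so an ideal
detector reports PPD = 2R and recovers the size exactly.  Backgrounds
sit near gray level 165 (real frames vary roughly 160–180 by sample
type) with an optional linear gradient, and sensor noise is additive
Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .imaging_io import DEFAULT_PIXEL_PITCH_UM, GrayImage
from .quantify import SIZE_COEFF_UM_PER_PX


def ring_radius_px(size_um: float, size_coeff: float = SIZE_COEFF_UM_PER_PX) -> float:
    """Ground-truth first-order ring radius for an object size (µm)."""
    return (size_um / size_coeff) / 2.0


@dataclass(frozen=True)
class ObjectSpec:
    """One rendered micro-object.

    ``center_level`` / ``annulus_depth`` / ``ring_gain`` are offsets from
    the local background (central lobe 20 levels below, annulus floor 35
    below, ring peak 15 above by default — inside the ranges measured on
    real bead/cell patterns).  Lobe widths default to the nearly
    size-independent values seen on real patterns (central half-width
    4 px, annulus 4 px, ring cross-section σ 2 px); for very small
    objects they are capped so the annulus stays inside the ring.
    """

    center: tuple[int, int]
    size_um: float
    center_drop: float = 20.0     # gray levels below background at r=0
    annulus_depth: float = 35.0   # gray levels below background at annulus floor
    ring_gain: float = 15.0       # gray levels above background at the ring peak
    central_half_width: float = 4.0
    annulus_width: float = 4.0
    ring_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not self.size_um > 0:
            raise ValueError("size_um must be > 0")

    @property
    def ring_radius(self) -> float:
        return ring_radius_px(self.size_um)

    @property
    def footprint_radius(self) -> float:
        """Radius beyond which the object no longer alters the frame."""
        return self.ring_radius + 4 * self.ring_sigma + 2


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic frame: background plane, objects, noise."""

    height: int = 1920
    width: int = 2560
    background_level: float = 165.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # total gray change (rows, cols)
    objects: tuple[ObjectSpec, ...] = ()
    noise_sigma: float = 2.0
    seed: int = 0
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame must be at least 1x1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        grad = self.background_gradient
        if np.isscalar(grad):
            object.__setattr__(self, "background_gradient", (0.0, float(grad)))
        object.__setattr__(self, "objects", tuple(self.objects))


@dataclass(frozen=True)
class TruthObject:
    center: tuple[int, int]
    size_um: float
    expected_ppd_px: float  # exactly 2R


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a rendered frame."""

    objects: tuple[TruthObject, ...]
    height: int
    width: int
    background_level: float
    background_gradient: tuple[float, float]
    noise_sigma: float
    seed: int

    @property
    def count(self) -> int:
        return len(self.objects)

    def to_json(self, path: str | Path) -> None:
        data = {
            "height": self.height,
            "width": self.width,
            "background_level": self.background_level,
            "background_gradient": list(self.background_gradient),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "objects": [
                {"center": list(o.center), "size_um": o.size_um,
                 "expected_ppd_px": o.expected_ppd_px}
                for o in self.objects
            ],
        }
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            objects=tuple(
                TruthObject(center=tuple(o["center"]), size_um=o["size_um"],
                            expected_ppd_px=o["expected_ppd_px"])
                for o in data["objects"]
            ),
            height=data["height"], width=data["width"],
            background_level=data["background_level"],
            background_gradient=tuple(data["background_gradient"]),
            noise_sigma=data["noise_sigma"], seed=data["seed"],
        )


def _validate_layout(spec: SceneSpec) -> None:
    for obj in spec.objects:
        r, c = obj.center
        if not (0 <= r < spec.height and 0 <= c < spec.width):
            raise ValueError(f"object center {obj.center} outside frame")
    if spec.allow_overlap:
        return
    objs = spec.objects
    for i in range(len(objs)):
        for j in range(i + 1, len(objs)):
            d = np.hypot(objs[i].center[0] - objs[j].center[0],
                         objs[i].center[1] - objs[j].center[1])
            min_d = objs[i].ring_radius + objs[j].ring_radius + 10
            if d <= min_d:
                raise ValueError(
                    f"objects {i} and {j} overlap (distance {d:.1f} <= {min_d:.1f}); "
                    "set allow_overlap to render anyway"
                )


def _object_offset(obj: ObjectSpec, r: np.ndarray) -> np.ndarray:
    """Radial intensity offset (gray levels, signed) of one object."""
    big_r = obj.ring_radius
    # cap lobe widths for small objects so the annulus stays inside the ring
    r1 = min(obj.central_half_width, 0.45 * big_r)
    w_a = min(obj.annulus_width, 0.3 * big_r)
    r_a = r1 + 1.0 + w_a / 2.0
    sigma_a = max(w_a / 1.5, 0.5)
    central = np.exp(-((r / max(r1, 0.5)) ** 6))
    annulus = np.exp(-(((r - r_a) / sigma_a) ** 4))
    ring = np.exp(-((r - big_r) ** 2) / (2.0 * obj.ring_sigma ** 2))
    return (-obj.center_drop * central
            - obj.annulus_depth * annulus * (1 - central)
            + obj.ring_gain * ring)


def render_scene(spec: SceneSpec) -> tuple[GrayImage, SceneTruth]:
    """Render a frame and its ground truth.

    The frame is a background plane (level + linear gradient) plus each
    object's radial profile plus seeded Gaussian noise, rounded and
    clipped to [0, 255].
    """
    _validate_layout(spec)
    h, w = spec.height, spec.width
    g_r, g_c = spec.background_gradient
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    frame = np.empty((h, w), dtype=np.float64)
    frame[:] = spec.background_level
    if g_r:
        frame += (g_r * rows / max(h - 1, 1))[:, None]
    if g_c:
        frame += (g_c * cols / max(w - 1, 1))[None, :]

    for obj in spec.objects:
        rad = int(np.ceil(obj.footprint_radius))
        r0, c0 = obj.center
        rlo, rhi = max(0, r0 - rad), min(h, r0 + rad + 1)
        clo, chi = max(0, c0 - rad), min(w, c0 + rad + 1)
        yy = rows[rlo:rhi, None] - r0
        xx = cols[None, clo:chi] - c0
        rr = np.hypot(yy, xx)
        frame[rlo:rhi, clo:chi] += _object_offset(obj, rr)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frame += rng.normal(0.0, spec.noise_sigma, size=frame.shape)

    pixels = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    truth = SceneTruth(
        objects=tuple(
            TruthObject(center=o.center, size_um=o.size_um,
                        expected_ppd_px=2.0 * o.ring_radius)
            for o in spec.objects
        ),
        height=h, width=w,
        background_level=spec.background_level,
        background_gradient=spec.background_gradient,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
    )
    return GrayImage(pixels, pixel_pitch=spec.pixel_pitch), truth


DEFAULT_SIZE_SET_UM = (5.0, 10.0, 20.0, 30.0)

#: Keep object centers at least this far from the frame border so their
#: rings (and the outward peak scan) stay inside the frame.
DEFAULT_BORDER_MARGIN_PX = 64


def place_objects(n: int, height: int, width: int, rng: np.random.Generator,
                  sizes_um: Sequence[float] = DEFAULT_SIZE_SET_UM,
                  margin: int = DEFAULT_BORDER_MARGIN_PX,
                  max_attempts: int = 20000) -> list[ObjectSpec]:
    """Seeded rejection-sampling placement honouring the separation rule
    (pairwise distance > R_i + R_j + 10 px) and a border margin."""
    if height - 2 * margin <= 0 or width - 2 * margin <= 0:
        raise ValueError("frame too small for the border margin")
    chosen_sizes = rng.choice(np.asarray(sizes_um, dtype=float), size=n)
    # place large objects first: easier packing, same seeded determinism
    chosen_sizes = np.sort(chosen_sizes)[::-1]
    placed: list[ObjectSpec] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    for size in chosen_sizes:
        radius = ring_radius_px(size)
        for _ in range(max_attempts):
            r = int(rng.integers(margin, height - margin))
            c = int(rng.integers(margin, width - margin))
            if len(placed):
                d = np.hypot(centers[:, 0] - r, centers[:, 1] - c)
                if np.any(d <= radii + radius + 10):
                    continue
            placed.append(ObjectSpec(center=(r, c), size_um=float(size)))
            centers = np.vstack([centers, [r, c]])
            radii = np.append(radii, radius)
            break
        else:
            raise ValueError(
                f"could not place {n} objects in {height}x{width} "
                f"(stuck after {len(placed)})"
            )
    return placed


def make_concentration_series(counts: Sequence[int],
                              base_spec: SceneSpec | None = None,
                              seed: int = 0,
                              sizes_um: Sequence[float] = DEFAULT_SIZE_SET_UM,
                              margin: int = DEFAULT_BORDER_MARGIN_PX,
                              ) -> list[tuple[GrayImage, SceneTruth]]:
    """Render one frame per requested object count.

    Placement and noise are seeded: the same ``seed`` reproduces
    bit-identical frames.  ``base_spec`` carries frame geometry,
    background, gradient and noise level; its object list is ignored.
    """
    base = base_spec or SceneSpec()
    if any(n < 1 for n in counts):
        raise ValueError("counts must be positive")
    out = []
    for i, n in enumerate(counts):
        frame_seed = int(seed) + i
        rng = np.random.default_rng(frame_seed)
        objects = place_objects(int(n), base.height, base.width, rng,
                                sizes_um=sizes_um, margin=margin)
        spec = replace(base, objects=tuple(objects), seed=frame_seed)
        out.append(render_scene(spec))
    return out
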