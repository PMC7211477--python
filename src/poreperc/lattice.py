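"""Synthetic square-grid lattice phantoms and their noise-degraded variants.

These phantoms emulate idealised micro-CT stacks of mesh-like porous
structures: every slice carries a square grid of solid lines (struts) with a
physical repeat distance ``D_repeat``; the space between the lines is open
pore.  Two families are produced:

* *aligned* — every slice identical, giving straight square channels along z;
* *shifted* — the grid origin moves by one pixel per slice along both
  in-plane axes, turning the channels into oblique (45°) pathways.

A controlled noise pipeline (slice-wise 3x3 mean smoothing, salt-and-pepper
inversion of a fixed fraction of each intensity class, Gaussian blur) can be
applied repeatedly to degrade the phantoms the way repeated acquisition
noise would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .volume import PORE_VALUE, STRUT_VALUE, VoxelVolume

LatticeKind = Literal["aligned", "shifted"]

AnomalyCorner = Literal[
    "top_left", "top_right", "bottom_left", "bottom_right", "centre"
]


@dataclass(frozen=True)
class MeshSpec:
    """Geometry of a synthetic lattice.

    ``repeat_distance_um`` is the physical grid spacing ``D_repeat``;
    ``pixel_size_um`` the simulated scan pixel size ``p``.  The volume is
    cubic by default (``slice_width_px`` defaults to ``n_slices``).
    """

    pixel_size_um: float
    repeat_distance_um: float
    lattice_kind: LatticeKind = "aligned"
    n_slices: int = 333
    slice_width_px: int | None = None
    strut_thickness_px: int = 1

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.repeat_distance_um > self.pixel_size_um:
            raise ValueError("repeat_distance_um must exceed pixel_size_um")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.strut_thickness_px < 1:
            raise ValueError("strut_thickness_px must be >= 1")
        if self.lattice_kind not in ("aligned", "shifted"):
            raise ValueError(f"unknown lattice kind {self.lattice_kind!r}")

    @property
    def repeat_px(self) -> float:
        """Grid repeat in pixels (may be non-integer)."""
        return self.repeat_distance_um / self.pixel_size_um

    @property
    def width_px(self) -> int:
        return self.slice_width_px if self.slice_width_px else self.n_slices


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one pass of the noise pipeline.

    ``invert_fraction`` of the dark pixels and, independently, of the bright
    pixels are flipped to the opposite extreme in each pass (the
    salt-and-pepper step).  ``blur_radius_px`` is the Gaussian sigma of the
    final smoothing step, in pixels.
    """

    passes: int = 1
    invert_fraction: float = 0.025
    blur_radius_px: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.passes < 0:
            raise ValueError("passes must be >= 0")
        if not 0.0 <= self.invert_fraction <= 1.0:
            raise ValueError("invert_fraction must lie in [0, 1]")
        if self.blur_radius_px < 0:
            raise ValueError("blur_radius_px must be >= 0")


def _grid_line_mask(width: int, repeat_px: float, thickness: int,
                    offset_px: float = 0.0) -> np.ndarray:
    """1D mask of strut-line pixels at average spacing ``repeat_px``.

    Lines are rasterised at ``round(k * repeat_px + offset)`` so the
    long-range average spacing equals the physical repeat even when the
    repeat is not an integer number of pixels.
    """
    mask = np.zeros(width, dtype=bool)
    lo = math.floor((-offset_px - thickness) / repeat_px) - 1
    hi = math.ceil((width - offset_px) / repeat_px) + 1
    for k in range(lo, hi + 1):
        start = round(k * repeat_px + offset_px)
        if start + thickness <= 0 or start >= width:
            continue
        mask[max(start, 0):min(start + thickness, width)] = True
    return mask


def generate_lattice(spec: MeshSpec) -> VoxelVolume:
    """Generate an aligned or shifted square-grid lattice volume.

    Strut pixels are white (255), pore pixels black (0).  For the shifted
    kind, slice ``k``'s grid origin is displaced by ``k`` pixels along both
    in-plane axes (one pixel size per slice), which wraps naturally modulo
    the repeat.  Deterministic.
    """
    if spec.repeat_px < 2:
        raise ValueError(
            "unresolvable mesh: repeat distance smaller than 2 pixels"
        )
    width = spec.width_px
    data = np.empty((spec.n_slices, width, width), dtype=np.uint8)
    cache: dict[float, np.ndarray] = {}
    for z in range(spec.n_slices):
        offset = float(z) if spec.lattice_kind == "shifted" else 0.0
        offset %= spec.repeat_px
        if offset not in cache:
            line = _grid_line_mask(
                width, spec.repeat_px, spec.strut_thickness_px, offset
            )
            slc = np.full((width, width), PORE_VALUE, dtype=np.uint8)
            slc[line, :] = STRUT_VALUE
            slc[:, line] = STRUT_VALUE
            cache[offset] = slc
        data[z] = cache[offset]
    return VoxelVolume(data, spec.pixel_size_um, "binary")


def apply_noise(volume: VoxelVolume, noise: NoiseSpec) -> VoxelVolume:
    """Degrade a volume with repeated smoothing / salt-and-pepper / blur.

    Each pass applies, in order: a slice-wise 3x3 mean filter (centre pixel
    included), inversion of ``invert_fraction`` of the dark (<128) and of
    the bright (>=128) pixels to 0/255 respectively, and a slice-wise
    Gaussian blur of sigma ``blur_radius_px``.  Bit-reproducible for a
    fixed ``rng_seed``.  ``passes=0`` returns the volume unchanged.
    """
    if volume.data.size == 0:
        raise ValueError("empty volume")
    if noise.passes == 0:
        return volume.with_data(volume.data.copy())
    rng = np.random.default_rng(noise.rng_seed)
    img = volume.data.astype(np.float64)
    for _ in range(noise.passes):
        # 1) slice-wise 3x3 mean including the centre pixel
        img = ndimage.uniform_filter(img, size=(1, 3, 3), mode="nearest")
        # 2) salt and pepper on the two intensity classes
        flat = img.reshape(-1)
        bright = flat >= 128.0
        for cls_mask, target in ((~bright, 255.0), (bright, 0.0)):
            idx = np.flatnonzero(cls_mask)
            n_invert = int(round(noise.invert_fraction * idx.size))
            if n_invert:
                chosen = rng.choice(idx, size=n_invert, replace=False)
                flat[chosen] = target
        img = flat.reshape(img.shape)
        # 3) slice-wise Gaussian blur
        if noise.blur_radius_px > 0:
            img = ndimage.gaussian_filter(
                img, sigma=(0, noise.blur_radius_px, noise.blur_radius_px),
                mode="nearest",
            )
    data = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return volume.with_data(data, encoding="grayscale")


def inject_anomaly(volume: VoxelVolume, channel_width_px: int,
                   corner: AnomalyCorner = "top_right") -> VoxelVolume:
    """Carve a straight through-thickness pore channel at a corner or centre.

    Used to plant a non-representative, anomalously wide pathway in an
    otherwise regular lattice, reproducing the situation where a single
    oversized pore on the edge of a region of interest dominates whole-ROI
    percolation.  ``channel_width_px = 0`` is the identity.
    """
    if channel_width_px == 0:
        return volume.with_data(volume.data.copy())
    if channel_width_px < 0:
        raise ValueError("channel_width_px must be >= 0")
    nz, ny, nx = volume.shape
    w = channel_width_px
    if w > ny or w > nx:
        raise ValueError("anomaly channel exceeds volume extent")
    if corner == "centre":
        y0, x0 = (ny - w) // 2, (nx - w) // 2
    elif corner == "top_left":
        y0, x0 = 0, 0
    elif corner == "top_right":
        y0, x0 = 0, nx - w
    elif corner == "bottom_left":
        y0, x0 = ny - w, 0
    elif corner == "bottom_right":
        y0, x0 = ny - w, nx - w
    else:
        raise ValueError(f"unknown corner {corner!r}")
    data = volume.data.copy()
    data[:, y0:y0 + w, x0:x0 + w] = PORE_VALUE
    return volume.with_data(data)
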