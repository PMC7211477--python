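"""Dimensioned voxel volumes.

A :class:`VoxelVolume` couples a 3D scalar grid (axis order z, y, x — slice,
row, column) with an isotropic pixel size ``p`` in micrometres.  The slice
axis ``z`` is the percolation direction; slice 0 is the "top" of the stack.
The encoding convention follows the usual micro-CT one for porous media:
black (0) voxels are empty pore space, white (maximum intensity) voxels are
solid struts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Encoding = Literal["binary", "grayscale"]

#: Names of the six faces of a volume; "top" is the z=0 slice.
FACES = ("top", "bottom", "y_min", "y_max", "x_min", "x_max")

PORE_VALUE = 0
STRUT_VALUE = 255


@dataclass
class VoxelVolume:
    """3D image with a physical pixel size.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities.  Binary volumes hold exactly two values, with 0
        marking pore space and the maximum marking solid material.
    pixel_size_um : float
        Isotropic edge length of one voxel in micrometres.
    encoding : {"binary", "grayscale"}
    """

    data: np.ndarray
    pixel_size_um: float
    encoding: Encoding = "binary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be 3D with all dims >= 1")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.encoding == "binary":
            vals = np.unique(self.data)
            if vals.size > 2:
                raise ValueError(
                    "binary volume contains more than two distinct values"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def depth_um(self) -> float:
        """Physical extent along the percolation (z) axis."""
        return self.n_slices * self.pixel_size_um

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um ** 3

    @property
    def total_volume_um3(self) -> float:
        return self.data.size * self.voxel_volume_um3

    # -- phase masks -----------------------------------------------------
    @property
    def pore_mask(self) -> np.ndarray:
        """Boolean mask of pore (black) voxels.  Binary volumes only."""
        self._require_binary()
        return self.data == PORE_VALUE

    @property
    def strut_mask(self) -> np.ndarray:
        self._require_binary()
        return self.data != PORE_VALUE

    def _require_binary(self) -> None:
        if self.encoding != "binary":
            raise ValueError("operation requires a binary volume")

    def with_data(self, data: np.ndarray, encoding: Encoding | None = None) -> "VoxelVolume":
        """Copy of this volume with new data (same pixel size)."""
        return replace(self, data=data, encoding=encoding or self.encoding)


def from_masks(pore: np.ndarray, pixel_size_um: float) -> VoxelVolume:
    """Build a binary volume from a boolean pore mask."""
    data = np.where(pore, PORE_VALUE, STRUT_VALUE).astype(np.uint8)
    return VoxelVolume(data, pixel_size_um, "binary")
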