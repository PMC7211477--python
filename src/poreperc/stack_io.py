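"""Reading, writing and conditioning of image stacks.

Stacks are stored the way desktop micro-CT software exports them: a
directory of equal-shaped 2D slices (TIFF/PNG/BMP, lexicographic order,
slice 0 = top) or a single multipage TIFF.  All conditioning operations
(thresholding, despeckling, VOI extraction, lateral sealing) preserve the
pixel size.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import PORE_VALUE, STRUT_VALUE, VoxelVolume

_SLICE_EXTENSIONS = (".tif", ".tiff", ".png", ".bmp")

#: 26-connectivity structuring element used by default for component labelling.
CONN26 = np.ones((3, 3, 3), dtype=bool)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def read_stack(path: str | Path, pixel_size_um: float) -> VoxelVolume:
    """Read a slice directory or a multipage TIFF into a voxel volume.

    Slices are ordered lexicographically; slice 0 is the top of the stack.
    Grayscale bit depth (8/16-bit) is preserved.
    """
    if pixel_size_um is None or not pixel_size_um > 0:
        raise ValueError("a positive pixel_size_um is required")
    path = Path(path)
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir()
            if f.suffix.lower() in _SLICE_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no image slices found in {path}")
        slices = []
        for f in files:
            img = np.asarray(iio.imread(f))
            if img.ndim == 3:  # collapse spurious colour axis
                img = img[..., 0]
            slices.append(img)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    elif path.is_file():
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
    else:
        raise ValueError(f"no such stack: {path}")
    vals = np.unique(data)
    encoding = "binary" if vals.size <= 2 else "grayscale"
    return VoxelVolume(data, pixel_size_um, encoding)


def write_stack(volume: VoxelVolume, path: str | Path,
                fmt: Literal["png", "tif"] = "png") -> list[Path]:
    """Write a volume as a numbered slice sequence; returns the file paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    written = []
    for z in range(data.shape[0]):
        f = path / f"slice_{z:05d}.{fmt}"
        iio.imwrite(f, data[z])
        written.append(f)
    return written


def otsu_threshold(volume: VoxelVolume) -> VoxelVolume:
    """Binarise with the global Otsu threshold of the whole-volume histogram.

    The threshold maximises between-class variance; voxels above it become
    strut (white), the rest pore (black).  Idempotent on binary input.
    """
    data = volume.data
    if data.min() == data.max():
        raise ValueError("no threshold: constant-intensity volume")
    thr = threshold_otsu(data)
    out = np.where(data > thr, STRUT_VALUE, PORE_VALUE).astype(np.uint8)
    return volume.with_data(out, encoding="binary")


def despeckle(volume: VoxelVolume, mode: Literal["sweep", "min_size"] = "sweep",
              min_size_vox: int = 1, connectivity: int = 26) -> VoxelVolume:
    """Remove disconnected speckles from a binary volume.

    ``sweep`` keeps only the largest connected strut component and the
    largest connected pore component (removed strut voxels become pore and
    vice versa).  ``min_size`` removes components smaller than
    ``min_size_vox`` voxels from both phases.
    """
    structure = _connectivity_structure(connectivity)
    pore = volume.pore_mask
    out = ~pore  # strut mask, modified in place

    def _filter(mask: np.ndarray) -> np.ndarray:
        """Return the voxels of `mask` to keep."""
        labels, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            return mask
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        if mode == "sweep":
            # components tying at the maximal size are all retained, so
            # regular structures with many equal channels are preserved
            keep = counts == counts.max()
            keep[0] = False
        elif mode == "min_size":
            keep = counts >= min_size_vox
            keep[0] = False
        else:
            raise ValueError(f"unknown despeckle mode {mode!r}")
        return keep[labels]

    out = _filter(out)          # small strut specks -> pore
    pore_kept = _filter(~out)   # small pore specks -> strut
    out = ~pore_kept
    data = np.where(out, STRUT_VALUE, PORE_VALUE).astype(np.uint8)
    return volume.with_data(data, encoding="binary")


def extract_voi(volume: VoxelVolume, origin_vox: Sequence[int],
                size_vox: Sequence[int]) -> VoxelVolume:
    """Copy a half-open box ``[origin, origin+size)`` (z, y, x order)."""
    origin = tuple(int(v) for v in origin_vox)
    size = tuple(int(v) for v in size_vox)
    if len(origin) != 3 or len(size) != 3:
        raise ValueError("origin_vox and size_vox must have three entries")
    if any(s <= 0 for s in size):
        raise ValueError("zero- or negative-size VOI")
    if any(o < 0 or o + s > dim
           for o, s, dim in zip(origin, size, volume.shape)):
        raise ValueError("VOI box out of bounds")
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return volume.with_data(volume.data[sl].copy())


def seal_lateral_faces(volume: VoxelVolume) -> VoxelVolume:
    """Insert a 1-voxel solid border on the four lateral faces of every slice.

    This restricts probe penetration to the two z faces, emulating seeding
    or infiltration from the top surface only.  Both z faces stay open.
    Idempotent.
    """
    volume._require_binary()
    data = volume.data.copy()
    data[:, 0, :] = STRUT_VALUE
    data[:, -1, :] = STRUT_VALUE
    data[:, :, 0] = STRUT_VALUE
    data[:, :, -1] = STRUT_VALUE
    return volume.with_data(data)


def save_masks(results, path: str | Path) -> None:
    """Write per-cluster-size accessibility masks as slice sequences.

    Masks use the standard post-shrink-wrap convention: open, interconnected
    (accessible) pore voxels black (0); struts and unreachable clusters
    white (255).
    """
    path = Path(path)
    for res in results:
        img = np.where(res.accessible_mask, PORE_VALUE, STRUT_VALUE)
        sub = path / f"cluster_{res.cluster_size:04d}"
        write_stack(
            VoxelVolume(img.astype(np.uint8), res.pixel_size_um, "binary"),
            sub,
        )


def load_masks(path: str | Path, pixel_size_um: float):
    """Read accessibility masks saved by :func:`save_masks`.

    Returns a list of ``(cluster_size, bool_mask)`` sorted by cluster size.
    """
    path = Path(path)
    out = []
    for sub in sorted(path.glob("cluster_*")):
        c = int(sub.name.split("_")[1])
        vol = read_stack(sub, pixel_size_um)
        out.append((c, vol.data == PORE_VALUE))
    if not out:
        raise ValueError(f"no saved masks under {path}")
    return out
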