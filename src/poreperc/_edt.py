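"""Exact Euclidean distance transforms on integer squared distances.

The accessibility and thickness algorithms threshold Euclidean distances
against half-integer probe radii (``c/2`` for a cluster of ``c`` voxels).
Working with *squared* integer distances makes every such comparison exact:
``dist >= c/2`` becomes ``4*dist2 >= c*c`` with no floating-point boundary
ambiguity.  The transform is the classic lower-envelope (parabola) algorithm
applied separably along the three axes, compiled with numba; it returns the
squared distance from every voxel to the nearest ``False`` voxel, treating
everything outside the array as ``True`` (no influence), which matches
``scipy.ndimage.distance_transform_edt`` semantics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Sentinel for "no background voxel anywhere" (kept well below int64 overflow).
NO_BACKGROUND = np.int64(1) << 50


@njit(cache=True)
def _dt1d(f, d, v, z, n):  # pragma: no cover - exercised via squared_edt
    """1D squared-distance transform of sampled function f, output in d."""
    k = 0
    v[0] = 0
    z[0] = -np.inf
    z[1] = np.inf
    for q in range(1, n):
        fq = f[q] + q * q
        s = (fq - (f[v[k]] + v[k] * v[k])) / (2.0 * (q - v[k]))
        while s <= z[k]:
            k -= 1
            s = (fq - (f[v[k]] + v[k] * v[k])) / (2.0 * (q - v[k]))
        k += 1
        v[k] = q
        z[k] = s
        z[k + 1] = np.inf
    k = 0
    for q in range(n):
        while z[k + 1] < q:
            k += 1
        d[q] = (q - v[k]) * (q - v[k]) + f[v[k]]


@njit(cache=True)
def _edt_sq_3d(fg):  # pragma: no cover - exercised via squared_edt
    nz, ny, nx = fg.shape
    out = np.empty((nz, ny, nx), np.int64)
    inf = NO_BACKGROUND
    # pass 1: exact 1D distance along z (binary input)
    for y in range(ny):
        for x in range(nx):
            dist = inf
            for zi in range(nz):
                if fg[zi, y, x] == 0:
                    dist = 0
                elif dist < inf:
                    dist += 1
                out[zi, y, x] = dist
            dist = inf
            for zi in range(nz - 1, -1, -1):
                if fg[zi, y, x] == 0:
                    dist = 0
                elif dist < inf:
                    dist += 1
                if dist < out[zi, y, x]:
                    out[zi, y, x] = dist
            for zi in range(nz):
                dcur = out[zi, y, x]
                if dcur < inf:
                    out[zi, y, x] = dcur * dcur
    # passes 2 and 3: parabola envelope along y then x
    f = np.empty(max(ny, nx), np.int64)
    d = np.empty(max(ny, nx), np.int64)
    v = np.empty(max(ny, nx), np.int64)
    z = np.empty(max(ny, nx) + 1, np.float64)
    for zi in range(nz):
        for x in range(nx):
            for y in range(ny):
                f[y] = out[zi, y, x]
            _dt1d(f, d, v, z, ny)
            for y in range(ny):
                out[zi, y, x] = d[y]
        for y in range(ny):
            for x in range(nx):
                f[x] = out[zi, y, x]
            _dt1d(f, d, v, z, nx)
            for x in range(nx):
                out[zi, y, x] = d[x]
    return out


def squared_edt(mask: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance from each voxel to the nearest False voxel.

    Parameters
    ----------
    mask : 3D bool array
        True marks the phase whose clearance is measured; False is background.

    Returns
    -------
    int64 array of the same shape.  Background voxels map to 0.  If the
    volume contains no background at all, every voxel maps to a value
    ``>= NO_BACKGROUND`` (effectively infinite clearance).
    """
    if mask.ndim != 3:
        raise ValueError("squared_edt expects a 3D array")
    return _edt_sq_3d(np.ascontiguousarray(mask, dtype=np.uint8))
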