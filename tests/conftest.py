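"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's distance-transform formulation:
accessibility is checked by enumerating every ball placement and walking the
adjacency graph of fitting centres; thickness by exhaustive
largest-inscribed-ball search.  Both use plain integer arithmetic.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np
import pytest

from poreperc.volume import FACES


def ball_offsets(c: int) -> list[tuple[int, int, int]]:
    """Voxel offsets of the digital ball of diameter c (4*|u|^2 < c^2)."""
    r = (c - 1) // 2 if c % 2 else c // 2  # offsets with 4*(dz2+dy2+dx2) < c2
    offs = []
    for dz, dy, dx in product(range(-r, r + 1), repeat=3):
        if 4 * (dz * dz + dy * dy + dx * dx) < c * c:
            offs.append((dz, dy, dx))
    return offs


def oracle_shrink_wrap(pore: np.ndarray, c: int,
                       entry_faces=FACES) -> np.ndarray:
    """All-ball-placements accessibility oracle.

    A centre fits when every voxel of its ball is pore; fitting centres are
    walked with 26-neighbour BFS from centres whose ball touches an entry
    face (face coordinate < c/2); the accessible set is the union of the
    reached centres' balls.
    """
    nz, ny, nx = pore.shape
    if c > min(pore.shape):
        return np.zeros_like(pore)
    offs = ball_offsets(c)
    fits = np.zeros_like(pore)
    for z, y, x in product(range(nz), range(ny), range(nx)):
        if not pore[z, y, x]:
            continue
        ok = True
        for dz, dy, dx in offs:
            u, v, w = z + dz, y + dy, x + dx
            if 0 <= u < nz and 0 <= v < ny and 0 <= w < nx and not pore[u, v, w]:
                ok = False
                break
        fits[z, y, x] = ok

    def touches_entry(z, y, x) -> bool:
        checks = {
            "top": 2 * z < c, "bottom": 2 * (nz - 1 - z) < c,
            "y_min": 2 * y < c, "y_max": 2 * (ny - 1 - y) < c,
            "x_min": 2 * x < c, "x_max": 2 * (nx - 1 - x) < c,
        }
        return any(checks[f] for f in entry_faces)

    seen = np.zeros_like(pore)
    queue: deque = deque()
    for z, y, x in zip(*np.nonzero(fits)):
        if touches_entry(z, y, x):
            seen[z, y, x] = True
            queue.append((int(z), int(y), int(x)))
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in product((-1, 0, 1), repeat=3):
            u, v, w = z + dz, y + dy, x + dx
            if (0 <= u < nz and 0 <= v < ny and 0 <= w < nx
                    and fits[u, v, w] and not seen[u, v, w]):
                seen[u, v, w] = True
                queue.append((u, v, w))

    accessible = np.zeros_like(pore)
    for z, y, x in zip(*np.nonzero(seen)):
        for dz, dy, dx in offs:
            u, v, w = z + dz, y + dy, x + dx
            if 0 <= u < nz and 0 <= v < ny and 0 <= w < nx:
                accessible[u, v, w] = True
    return accessible & pore


def oracle_local_thickness(phase: np.ndarray) -> np.ndarray:
    """Exhaustive largest-inscribed-ball thickness, in voxel diameters.

    Each candidate centre w carries the maximal open ball of radius equal
    to the distance to the nearest non-phase voxel (volume border counts as
    surface); each phase voxel gets the largest diameter 2*r over balls
    containing it.
    """
    nz, ny, nx = phase.shape
    bg = [(z, y, x) for z, y, x in product(range(-1, nz + 1),
                                           range(-1, ny + 1),
                                           range(-1, nx + 1))
          if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx)
          or not phase[z, y, x]]
    bg = np.array(bg)
    thick = np.zeros(phase.shape)
    centres = np.argwhere(phase)
    r2 = np.empty(len(centres))
    for k, w in enumerate(centres):
        r2[k] = ((bg - w) ** 2).sum(axis=1).min()
    for k, w in enumerate(centres):
        for v in centres[((centres - w) ** 2).sum(axis=1) < r2[k]]:
            d = 2.0 * np.sqrt(r2[k])
            if d > thick[tuple(v)]:
                thick[tuple(v)] = d
    return thick


def oracle_otsu(data: np.ndarray) -> tuple[int, int]:
    """Exhaustive between-class-variance maximisation over 8-bit thresholds.

    Returns the (inclusive) range of thresholds t achieving the maximum,
    where class split is (<= t, > t).
    """
    flat = data.ravel().astype(np.float64)
    best, args = -1.0, []
    for t in range(256):
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best + 1e-9:
            best, args = var, [t]
        elif abs(var - best) <= 1e-9:
            args.append(t)
    return min(args), max(args)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def aligned_small():
    """Aligned lattice, integer repeat 10 px at p=6 um, 40^3."""
    from poreperc import MeshSpec, generate_lattice

    return generate_lattice(
        MeshSpec(pixel_size_um=6.0, repeat_distance_um=60.0,
                 lattice_kind="aligned", n_slices=40, slice_width_px=40)
    )


def make_funnel(R=12, W=72, n_slices=60, w_top=11, narrow_every=10,
                pixel_size_um=6.0):
    """Aligned grid whose struts thicken with depth (funnel channels).

    Channel width at slice z is ``w_top - z // narrow_every``; probes
    penetrate until the channel narrows below their passable width, giving
    a graded, exactly derivable penetration-depth profile.
    """
    from poreperc.volume import from_masks

    vol = np.zeros((n_slices, W, W), np.uint8)
    for z in range(n_slices):
        t = R - funnel_width(z, w_top, narrow_every)
        line = np.zeros(W, bool)
        for k in range(0, W // R + 1):
            line[k * R:k * R + t] = True
        sl = np.zeros((W, W), np.uint8)
        sl[line, :] = 255
        sl[:, line] = 255
        vol[z] = sl
    return from_masks(vol == 0, pixel_size_um)


def funnel_width(z: int, w_top: int = 11, narrow_every: int = 10) -> int:
    return w_top - z // narrow_every


def passable(c: int, w: int) -> bool:
    """A c-voxel digital ball fits a straight w-wide channel iff 2*ceil(w/2) >= c."""
    return 2 * ((w + 1) // 2) >= c


@pytest.fixture(scope="session")
def funnel_sealed():
    from poreperc import seal_lateral_faces

    return seal_lateral_faces(make_funnel())


@pytest.fixture(scope="session")
def funnel_series(funnel_sealed):
    from poreperc import ClusterRange, shrink_wrap_series

    return shrink_wrap_series(funnel_sealed, ClusterRange(2, 16, 1),
                              ("top", "bottom"))


@pytest.fixture(scope="session")
def shifted_small():
    """Shifted lattice with non-integer repeat (graded penetration), 64^3."""
    from poreperc import MeshSpec, generate_lattice

    return generate_lattice(
        MeshSpec(pixel_size_um=3.0, repeat_distance_um=40.0,
                 lattice_kind="shifted", n_slices=64, slice_width_px=64)
    )
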