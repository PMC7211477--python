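"""Regeneration of the artificial-lattice pore-size studies.

These routines rebuild the synthetic study grid — square-grid lattices at
simulated pixel sizes 1.5, 3 and 6 um with repeat distances 40–120 um —
measure mean pore size by maximal-inscribed-sphere thickness, and reduce
the measurements to the two summary statistics that characterise the
lattice families:

* aligned lattices: the pooled least-squares slope of mean pore size on
  repeat distance (close to 0.9 — straight square channels read slightly
  below their repeat because strut walls subtract a pixel and sphere
  fitting under-covers channel corners);
* shifted lattices: the mean ratio of repeat distance to mean pore size
  (about 1.6 — the one-pixel-per-slice shift tilts the channels 45 degrees,
  shrinking the inscribed-sphere diameter by roughly 1/sqrt(2)).

Volumes default to 200^3 voxels, which preserves several grid repeats at
every pixel size while keeping the sphere-fitting granulometry tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accessibility import local_thickness
from .lattice import MeshSpec, generate_lattice

PIXEL_SIZES_UM = (1.5, 3.0, 6.0)
REPEAT_DISTANCES_UM = (40.0, 60.0, 80.0, 100.0, 120.0)


@dataclass
class PoreSizeStudy:
    """Mean pore sizes over the (pixel size, repeat distance) grid."""

    lattice_kind: str
    pixel_sizes_um: tuple[float, ...]
    repeat_distances_um: tuple[float, ...]
    mean_pore_um: dict[tuple[float, float], float]

    @property
    def pooled_slope(self) -> float:
        """Least-squares slope of mean pore size on repeat distance,
        pooled across pixel sizes."""
        d = np.array([D for (_, D) in self.mean_pore_um])
        m = np.array(list(self.mean_pore_um.values()))
        slope, _ = np.polyfit(d, m, 1)
        return float(slope)

    @property
    def mean_repeat_ratio(self) -> float:
        """Mean of D_repeat / mean pore size across the grid."""
        ratios = [D / m for (_, D), m in self.mean_pore_um.items()]
        return float(np.mean(ratios))


def pore_size_study(lattice_kind: str = "aligned",
                    n_vox: int = 200,
                    pixel_sizes_um: tuple[float, ...] = PIXEL_SIZES_UM,
                    repeat_distances_um: tuple[float, ...] = REPEAT_DISTANCES_UM,
                    ) -> PoreSizeStudy:
    """Generate the lattice grid and measure mean pore sizes.

    ``n_vox`` sets the cubic volume edge in voxels.  Deterministic.
    """
    means: dict[tuple[float, float], float] = {}
    for p in pixel_sizes_um:
        for D in repeat_distances_um:
            spec = MeshSpec(pixel_size_um=p, repeat_distance_um=D,
                            lattice_kind=lattice_kind, n_slices=n_vox,
                            slice_width_px=n_vox)
            vol = generate_lattice(spec)
            stats = local_thickness(vol, "pore")
            means[(p, D)] = stats.mean_um
    return PoreSizeStudy(
        lattice_kind=lattice_kind,
        pixel_sizes_um=tuple(pixel_sizes_um),
        repeat_distances_um=tuple(repeat_distances_um),
        mean_pore_um=means,
    )
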