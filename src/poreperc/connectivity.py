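"""Interconnectivity curves and the median interconnection diameter.

The percentage interconnectivity at probe diameter ``d`` is the fraction of
pore volume still accessible to a spherical probe of that diameter:

    I = 100 * (V - V_c) / (V - V_m)

where ``V`` is the VOI volume, ``V_m`` the solid volume and ``V_c`` the
non-accessible volume after the shrink-wrap at that probe size.  The median
interconnection diameter ``d_median`` is the probe diameter at which exactly
half the pore volume remains accessible, obtained by linear interpolation of
the measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .accessibility import ShrinkWrapResult


def interconnectivity(result: ShrinkWrapResult) -> float:
    """Percentage of pore volume accessible at this probe size."""
    V, V_m, V_c = result.V_um3, result.V_m_um3, result.V_c_um3
    if not V > V_m:
        raise ValueError("no pore phase: V == V_m")
    return 100.0 * (V - V_c) / (V - V_m)


@dataclass
class InterconnectivityCurve:
    """Interconnectivity ``I`` (percent) against probe diameter ``d`` (um)."""

    d_um: np.ndarray
    I_percent: np.ndarray
    V_um3: float
    V_m_um3: float

    def __post_init__(self) -> None:
        self.d_um = np.asarray(self.d_um, dtype=float)
        self.I_percent = np.asarray(self.I_percent, dtype=float)
        if self.d_um.size != self.I_percent.size or self.d_um.size == 0:
            raise ValueError("curve needs matching, non-empty d and I arrays")
        if np.any(np.isnan(self.d_um)) or np.any(np.isnan(self.I_percent)):
            raise ValueError("NaN in interconnectivity curve")
        if np.any(np.diff(self.d_um) <= 0):
            raise ValueError("probe diameters must be strictly increasing")

    @property
    def d_median_um(self) -> float | None:
        return median_interconnection_diameter(self)

    def to_frame(self, pixel_size_um: float | None = None) -> pd.DataFrame:
        """Tabulate the curve (with cluster sizes when ``p`` is given)."""
        df = pd.DataFrame({"d_um": self.d_um, "I_percent": self.I_percent})
        if pixel_size_um:
            df.insert(0, "cluster_size",
                      np.rint(self.d_um / pixel_size_um).astype(int))
        return df


def interconnectivity_curve(results: Sequence[ShrinkWrapResult]
                            ) -> InterconnectivityCurve:
    """Assemble the I(d) curve from a shrink-wrap series."""
    if not results:
        raise ValueError("no shrink-wrap results")
    ordered = sorted(results, key=lambda r: r.cluster_size)
    return InterconnectivityCurve(
        d_um=np.array([r.probe_diameter_um for r in ordered]),
        I_percent=np.array([interconnectivity(r) for r in ordered]),
        V_um3=ordered[0].V_um3,
        V_m_um3=ordered[0].V_m_um3,
    )


def median_interconnection_diameter(curve: InterconnectivityCurve
                                    ) -> float | None:
    """Probe diameter at 50% interconnectivity, or None when not bracketed.

    Uses linear interpolation between the first pair of neighbouring points
    that bracket 50%; an exact 50% measurement returns its own diameter.
    The value is undefined (None, not an error) when the measured curve
    never crosses 50% — e.g. when the sample was imaged at too high or too
    low a pixel size for the accessible probe-diameter window.
    """
    d, I = curve.d_um, curve.I_percent
    for i in range(d.size):
        if I[i] == 50.0:
            return float(d[i])
        if i + 1 < d.size and (I[i] - 50.0) * (I[i + 1] - 50.0) < 0:
            t = (50.0 - I[i]) / (I[i + 1] - I[i])
            return float(d[i] + t * (d[i + 1] - d[i]))
    return None
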