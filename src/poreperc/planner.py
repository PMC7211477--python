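"""Acquisition pixel-size planning for percolation analysis.

Choosing the scan pixel size ``p`` is a three-way balance:

* *computation* — the largest probe the software can run, ``c_max`` voxels,
  must still encompass the largest pore expected (mean + 2 sd at the ~95%
  level), giving a lower bound ``p_comp``;
* *resolution* — the smallest probe, ``c_min`` voxels, must be finer than
  the smallest feature that matters (the smallest expected pore, or the
  fenestration size ``D_fen`` when those openings are relevant to the
  percolating object), giving an upper bound ``p_res``;
* *regression* — extrapolating ``d_perc`` needs ``n_data`` usable probe
  sizes beyond the feature size, which shrinks the usable cluster range to
  ``c_max,data = c_max - g_c * n_data`` and ``c_min,data = c_min + g_c * n_data``.

The admissible window is then

    (D_pore + 2 sigma) / (c_max - g_c n_data)  <  p  <  (D_pore - 2 sigma) / (c_min + g_c n_data)

with the resolution bound replaced by ``D_fen / c_min`` when fenestrations
govern.  Separately, the physical probe emulating a real percolating object
fixes ``p_experiment = d_probe / c_min`` with ``d_probe`` equal to the
object size (rigid objects) or its smallest stable protrusion size
(compressible objects such as migrating cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class PlannerInputs:
    """Structure and analysis parameters for pixel-size planning.

    Lengths in micrometres: ``D_pore`` mean pore size, ``sigma_pore`` its
    standard deviation, ``D_fen`` the smallest connection (fenestration)
    size, ``d_object`` the size of the real percolating object and
    ``d_protrusion`` the smallest stable protrusion of a compressible
    object.  Cluster-schedule counts as in :class:`~poreperc.accessibility.ClusterRange`;
    ``n_data`` is the number of regression points required.
    """

    D_pore_um: float
    sigma_pore_um: float = 0.0
    D_fen_um: Optional[float] = None
    d_object_um: Optional[float] = None
    d_protrusion_um: Optional[float] = None
    c_min: int = 2
    c_max: int = 100
    g_c: int = 2
    n_data: int = 6

    def __post_init__(self) -> None:
        for name in ("D_pore_um", "D_fen_um", "d_object_um", "d_protrusion_um"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when given")
        if self.sigma_pore_um < 0:
            raise ValueError("sigma_pore_um must be >= 0")
        if not self.c_min < self.c_max:
            raise ValueError("need c_min < c_max")
        if self.n_data < 0 or self.g_c < 1:
            raise ValueError("need n_data >= 0 and g_c >= 1")


@dataclass
class PixelWindow:
    """Admissible open pixel-size interval (p_comp, p_res) with diagnostics."""

    p_comp_um: float             # lower bound (computation constraint)
    p_res_um: float              # upper bound (resolution constraint)
    c_max_data: int
    c_min_data: int
    feasible: bool
    resolution_governed_by: str  # "pore_size" or "fenestration"
    d_probe_um: Optional[float] = None     # target physical probe, if planned
    p_experiment_um: Optional[float] = None

    @property
    def p_analysis_um(self) -> tuple[float, float]:
        """The open interval p_comp < p < p_res."""
        return (self.p_comp_um, self.p_res_um)

    def rounded(self, decimals: int = 1) -> tuple[float, float]:
        """Bounds rounded for display (full precision is kept internally)."""
        return (round(self.p_comp_um, decimals), round(self.p_res_um, decimals))


def probe_diameter(p_um: float, c_min: int = 2) -> float:
    """Smallest physical probe usable at pixel size p: d_probe = p * c_min."""
    if not p_um > 0:
        raise ValueError("pixel size must be positive")
    return p_um * c_min


def admissible_pixel_window(inputs: PlannerInputs,
                            fenestrations_relevant: bool = False
                            ) -> PixelWindow:
    """Admissible pixel-size window under computation, resolution and
    regression constraints.

    ``fenestrations_relevant`` selects the ``p_res = D_fen / c_min`` branch
    (small compressible objects that can exploit fenestrations); otherwise
    the smallest expected pore ``D_pore - 2 sigma`` governs resolution.
    Infeasible windows are returned with ``feasible=False``, not raised.
    """
    c_max_data = inputs.c_max - inputs.g_c * inputs.n_data
    c_min_data = inputs.c_min + inputs.g_c * inputs.n_data
    if c_max_data <= 0:
        raise ValueError(
            "regression consumes cluster budget: c_max - g_c*n_data <= 0"
        )
    p_comp = (inputs.D_pore_um + 2.0 * inputs.sigma_pore_um) / c_max_data
    if fenestrations_relevant:
        if inputs.D_fen_um is None:
            raise ValueError("fenestrations_relevant requires D_fen_um")
        p_res = inputs.D_fen_um / inputs.c_min
        governed = "fenestration"
    else:
        p_res = (inputs.D_pore_um - 2.0 * inputs.sigma_pore_um) / c_min_data
        governed = "pore_size"
    return PixelWindow(
        p_comp_um=p_comp, p_res_um=p_res,
        c_max_data=c_max_data, c_min_data=c_min_data,
        feasible=p_comp < p_res,
        resolution_governed_by=governed,
    )


def plan_for_object(inputs: PlannerInputs, compressible: bool = False,
                    fenestrations_relevant: bool = False) -> PixelWindow:
    """Pixel size emulating a real percolating object, checked against the
    analysis window.

    Rigid objects probe with their own diameter (``d_probe = d_object``);
    compressible objects probe with their smallest stable protrusion
    (``d_probe = d_protrusion``).  The experiment pixel size is
    ``p_experiment = d_probe / c_min``; the plan is feasible iff it falls
    strictly inside the open analysis window.
    """
    if inputs.d_object_um is None:
        raise ValueError("plan_for_object requires d_object_um")
    if compressible:
        if inputs.d_protrusion_um is None:
            raise ValueError("compressible object requires d_protrusion_um")
        d_probe = inputs.d_protrusion_um
    else:
        d_probe = inputs.d_object_um
    window = admissible_pixel_window(inputs, fenestrations_relevant)
    p_exp = d_probe / inputs.c_min
    window.d_probe_um = d_probe
    window.p_experiment_um = p_exp
    window.feasible = window.p_comp_um < p_exp < window.p_res_um
    return window
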