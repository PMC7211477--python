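"""Percolation-diameter extraction from shrink-wrap mask stacks.

The percolation diameter ``d_perc`` is the diameter of the largest sphere
able to traverse an infinitely extended structure.  It is extrapolated from
finite penetration depths: for each probe diameter ``d`` the depth ``L`` of
the accessible pore column (distance from a z surface to the first entirely
blank slice of the post-shrink-wrap mask) follows the critical scaling law

    L = L0 * (d - d_perc) ** (-nu),       nu = 0.88 in 3D,

so ordinary least squares of ``L**(-1/nu)`` on ``d`` has its x-intercept at
``d_perc``.  The segmented (ROI-subdivision) variant repeats the fit on
progressively smaller crops of the saved masks and selects the percolation
diameter with the longest plateau across crop sizes, which suppresses the
influence of anomalous, non-representative pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .accessibility import ClusterRange, ShrinkWrapResult, shrink_wrap_series
from .volume import VoxelVolume

NU_3D = 0.88  # critical scaling exponent for 3D percolation

Direction = Literal["top", "bottom"]
Method = Literal["centre", "left"]


class FitError(ValueError):
    """Raised when a percolation fit is impossible on the given points."""


@dataclass
class DepthProfile:
    """Penetration depths per probe size, measured from both z surfaces."""

    cluster_sizes: np.ndarray
    d_um: np.ndarray
    L_top_um: np.ndarray
    L_bot_um: np.ndarray
    full_depth_um: float
    pixel_size_um: float
    full_percolation_top: np.ndarray
    full_percolation_bot: np.ndarray
    zero_penetration_top: np.ndarray
    zero_penetration_bot: np.ndarray

    def depths(self, direction: Direction) -> np.ndarray:
        return self.L_top_um if direction == "top" else self.L_bot_um

    def usable(self, direction: Direction) -> np.ndarray:
        """Points with partial penetration (neither saturated nor blocked)."""
        if direction == "top":
            return ~(self.full_percolation_top | self.zero_penetration_top)
        return ~(self.full_percolation_bot | self.zero_penetration_bot)


@dataclass
class PercolationFit:
    """Result of the critical-scaling-law regression."""

    d_perc_um: float
    nu: float
    L0_um: float
    r_squared: float
    n_points_used: int

    @property
    def physical(self) -> bool:
        """Negative intercepts do not represent a physical diameter."""
        return self.d_perc_um > 0


@dataclass
class SubdivisionIteration:
    i: int
    R_px: int
    fit: PercolationFit | None   # None when the fit failed on this crop


@dataclass
class SubdivisionTrace:
    """Per-iteration percolation fits for one subdivision method/direction."""

    method: Method
    direction: Direction
    g_sub: int
    iterations: list[SubdivisionIteration]


@dataclass
class PlateauChoice:
    value_um: float
    length: int
    R_range_px: tuple[int, int]


@dataclass
class StableDiameter:
    """Longest-plateau percolation diameter, robust to ROI subdivision."""

    d_perc_stable_um: float
    plateau_length: int
    plateau_R_range_px: tuple[int, int]
    per_trace: dict[tuple[str, str], PlateauChoice]
    per_method_mean_um: dict[str, float]
    per_method_sd_um: dict[str, float]


# ---------------------------------------------------------------------------
# depths
# ---------------------------------------------------------------------------

def percolation_depths(results: Sequence[ShrinkWrapResult],
                       mode: Literal["sealed", "open"] = "sealed"
                       ) -> DepthProfile:
    """Measure L_top and L_bot from post-shrink-wrap masks.

    A slice is *blank* when it contains no accessible voxels; ``L_top`` is
    the distance from the top surface to the first blank slice (``L_bot``
    symmetric from the bottom).  In ``open`` mode — unmodified VOIs probed
    from all faces — accessible voxels within ``ceil(c/2)`` voxels of a
    lateral face are disregarded first, so slices where only surface pores
    are reachable count as blank.  Stacks with no blank slice are flagged
    ``full_percolation`` (L = full depth); stacks whose first slice is
    already blank are flagged ``zero_penetration`` (L = 0).
    """
    if not results:
        raise ValueError("empty mask sequence")
    shapes = {r.accessible_mask.shape for r in results}
    pixels = {r.pixel_size_um for r in results}
    if len(shapes) != 1 or len(pixels) != 1:
        raise ValueError("masks must share shape and pixel size")
    ordered = sorted(results, key=lambda r: r.cluster_size)
    p = ordered[0].pixel_size_um
    nz = ordered[0].accessible_mask.shape[0]
    full_depth = nz * p

    cs, ds = [], []
    L_top, L_bot, fp_t, fp_b, zp_t, zp_b = [], [], [], [], [], []
    for res in ordered:
        mask = res.accessible_mask
        if mode == "open":
            shell = math.ceil(res.cluster_size / 2)
            mask = mask.copy()
            mask[:, :shell, :] = False
            mask[:, -shell:, :] = False
            mask[:, :, :shell] = False
            mask[:, :, -shell:] = False
        counts = mask.reshape(nz, -1).any(axis=1)
        blank = np.flatnonzero(~counts)
        cs.append(res.cluster_size)
        ds.append(res.probe_diameter_um)
        if blank.size == 0:
            L_top.append(full_depth); fp_t.append(True); zp_t.append(False)
            L_bot.append(full_depth); fp_b.append(True); zp_b.append(False)
        else:
            k_top, k_bot = int(blank[0]), int(blank[-1])
            L_top.append(k_top * p)
            fp_t.append(False)
            zp_t.append(k_top == 0)
            L_bot.append((nz - 1 - k_bot) * p)
            fp_b.append(False)
            zp_b.append(k_bot == nz - 1)
    return DepthProfile(
        cluster_sizes=np.array(cs), d_um=np.array(ds),
        L_top_um=np.array(L_top), L_bot_um=np.array(L_bot),
        full_depth_um=full_depth, pixel_size_um=p,
        full_percolation_top=np.array(fp_t), full_percolation_bot=np.array(fp_b),
        zero_penetration_top=np.array(zp_t), zero_penetration_bot=np.array(zp_b),
    )


# ---------------------------------------------------------------------------
# scaling-law regression
# ---------------------------------------------------------------------------

def fit_percolation(profile: DepthProfile, direction: Direction = "top",
                    nu: float = NU_3D, n_data_min: int = 6,
                    include_flagged: bool = False) -> PercolationFit:
    """Fit L = L0 (d - d_perc)^-nu by OLS of ``L**(-1/nu)`` on ``d``.

    Saturated points (full percolation) and fully blocked points (zero
    penetration) carry no depth information about the transition and are
    excluded unless ``include_flagged``.  A non-positive fitted ``d_perc``
    is returned as-is but flagged unphysical via :attr:`PercolationFit.physical`.
    """
    if not nu > 0:
        raise ValueError("nu must be positive")
    use = np.ones(profile.d_um.size, bool) if include_flagged \
        else profile.usable(direction)
    L = profile.depths(direction)
    use = use & (L > 0)
    d = profile.d_um[use]
    y = L[use] ** (-1.0 / nu)
    if d.size < n_data_min:
        raise FitError(
            f"too few usable points for regression ({d.size} < {n_data_min})"
        )
    res = stats.linregress(d, y)
    if not res.slope > 0:
        raise FitError("non-decreasing depths: regression slope <= 0")
    d_perc = -res.intercept / res.slope
    return PercolationFit(
        d_perc_um=float(d_perc), nu=nu,
        L0_um=float(res.slope ** -nu),
        r_squared=float(res.rvalue ** 2),
        n_points_used=int(d.size),
    )


# ---------------------------------------------------------------------------
# ROI subdivision of saved masks
# ---------------------------------------------------------------------------

def subdivision_sizes(R0: int, g_sub: int) -> list[tuple[int, int]]:
    """Iteration schedule [(i, R_i)] with R_i = round(R0 - i*R0/g_sub).

    Stops before R_i drops below 2 pixels.  i = 0 is the uncropped ROI.
    """
    if g_sub < 2:
        raise ValueError("g_sub must be >= 2")
    out: list[tuple[int, int]] = []
    for i in range(g_sub):
        R_i = int(math.floor(R0 - i * R0 / g_sub + 0.5))  # round half up
        if R_i < 2:
            break
        if out and R_i >= out[-1][1]:  # keep R_i strictly decreasing
            continue
        out.append((i, R_i))
    return out


def crop_masks(masks: Sequence[np.ndarray], method: Method, R_i: int
               ) -> list[np.ndarray]:
    """In-plane square crops of side R_i of every mask in the stack.

    ``centre`` crops share the centre of the original ROI (anchor
    ``floor((R0 - R_i)/2)``); ``left`` crops share the top-left corner.
    """
    R0 = masks[0].shape[1]
    if masks[0].shape[1] != masks[0].shape[2]:
        raise ValueError("subdivision requires square in-plane masks")
    if method == "centre":
        a = (R0 - R_i) // 2
    elif method == "left":
        a = 0
    else:
        raise ValueError(f"unknown subdivision method {method!r}")
    return [m[:, a:a + R_i, a:a + R_i] for m in masks]


def subdivide_roi(masks: Sequence[np.ndarray], method: Method, g_sub: int
                  ) -> list[tuple[int, int, list[np.ndarray]]]:
    """Crops of the saved post-shrink-wrap masks at every subdivision step.

    Operates purely on saved masks — accessibility is *not* recomputed per
    sub-ROI.  Returns ``[(i, R_i, cropped_masks), ...]``.
    """
    R0 = masks[0].shape[1]
    return [(i, R_i, crop_masks(masks, method, R_i))
            for i, R_i in subdivision_sizes(R0, g_sub)]


# ---------------------------------------------------------------------------
# plateau selection
# ---------------------------------------------------------------------------

def _round_to_pixel(value_um: float, p_um: float) -> float:
    """Round to the nearest multiple of the pixel size (half away from zero)."""
    return math.floor(value_um / p_um + 0.5) * p_um


def _longest_run(values: list[float], R: list[int]) -> PlateauChoice | None:
    """Longest run of consecutive identical values; ties go to larger R_i."""
    if not values:
        return None
    best: PlateauChoice | None = None
    start = 0
    for k in range(1, len(values) + 1):
        if k == len(values) or values[k] != values[start]:
            length = k - start
            if best is None or length > best.length:
                best = PlateauChoice(
                    value_um=values[start], length=length,
                    R_range_px=(R[start], R[k - 1]),
                )
            start = k
    return best


def select_stable_diameter(traces: Iterable[SubdivisionTrace], p_um: float
                           ) -> StableDiameter:
    """Longest-plateau selection of the stable percolation diameter.

    Per trace: fitted diameters are rounded to the nearest multiple of the
    pixel size (the intrinsic resolution limit), non-positive values are
    dropped, and the longest run of identical consecutive values over
    decreasing R_i is taken.  Ties are broken toward the plateau at larger
    R_i.  The overall stable diameter is the longest plateau across all
    traces.
    """
    traces = list(traces)
    per_trace: dict[tuple[str, str], PlateauChoice] = {}
    for tr in traces:
        vals, Rs = [], []
        for it in tr.iterations:
            if it.fit is None:
                continue
            v = _round_to_pixel(it.fit.d_perc_um, p_um)
            if v > 0:
                vals.append(v)
                Rs.append(it.R_px)
        choice = _longest_run(vals, Rs)
        if choice is not None:
            per_trace[(tr.method, tr.direction)] = choice
    if not per_trace:
        raise ValueError(
            "no stable percolation diameter: no positive fitted diameters"
        )
    best_key = max(
        per_trace,
        key=lambda k: (per_trace[k].length, per_trace[k].R_range_px[0]),
    )
    best = per_trace[best_key]
    methods = {m for m, _ in per_trace}
    mean_um, sd_um = {}, {}
    for m in methods:
        vs = [c.value_um for (mm, _), c in per_trace.items() if mm == m]
        mean_um[m] = float(np.mean(vs))
        sd_um[m] = float(np.std(vs))
    return StableDiameter(
        d_perc_stable_um=best.value_um,
        plateau_length=best.length,
        plateau_R_range_px=best.R_range_px,
        per_trace=per_trace,
        per_method_mean_um=mean_um,
        per_method_sd_um=sd_um,
    )


# ---------------------------------------------------------------------------
# end-to-end segmented percolation
# ---------------------------------------------------------------------------

def segmented_percolation(volume: VoxelVolume, clusters: ClusterRange,
                          g_sub: int = 20,
                          methods: Sequence[Method] = ("centre", "left"),
                          nu: float = NU_3D,
                          mode: Literal["sealed", "open"] = "sealed",
                          entry_faces: Iterable[str] | None = None,
                          n_data_min: int = 6,
                          results: Sequence[ShrinkWrapResult] | None = None,
                          ) -> tuple[StableDiameter, list[SubdivisionTrace]]:
    """Shrink-wrap, subdivide the saved masks, fit, and select the plateau.

    ``results`` may carry a precomputed shrink-wrap series (e.g. reloaded
    from disk) to skip the accessibility step.  Raises ``ValueError`` when
    no subdivision yields a positive percolation diameter — the honest
    outcome for structures with all-or-nothing percolation.
    """
    if results is None:
        results = shrink_wrap_series(volume, clusters, entry_faces)
    p = volume.pixel_size_um
    masks = [r.accessible_mask for r in results]
    sizes = [r.cluster_size for r in results]
    traces: list[SubdivisionTrace] = []
    for method in methods:
        iters: dict[Direction, list[SubdivisionIteration]] = {
            "top": [], "bottom": [],
        }
        for i, R_i, cropped in subdivide_roi(masks, method, g_sub):
            sub_results = [
                ShrinkWrapResult(
                    cluster_size=c, pixel_size_um=p, accessible_mask=m,
                    V_um3=m.size * p ** 3, V_m_um3=0.0, V_c_um3=0.0,
                )
                for c, m in zip(sizes, cropped)
            ]
            profile = percolation_depths(sub_results, mode=mode)
            for direction in ("top", "bottom"):
                try:
                    fit = fit_percolation(
                        profile, direction=direction, nu=nu,
                        n_data_min=n_data_min,
                    )
                except FitError:
                    fit = None
                iters[direction].append(SubdivisionIteration(i, R_i, fit))
        for direction in ("top", "bottom"):
            traces.append(SubdivisionTrace(
                method=method, direction=direction, g_sub=g_sub,
                iterations=iters[direction],
            ))
    stable = select_stable_diameter(traces, p)
    return stable, traces
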