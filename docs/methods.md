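# Methods

This note records the models, conventions and numerical choices behind
`poreperc`, and what the synthetic validation does and does not establish.

## Voxel model and conventions

Volumes are 3D scalar grids in (z, y, x) order with an isotropic pixel size
*p* in µm; z is the percolation direction and slice 0 the "top". Binary
volumes encode pore space as black (0) and solid struts as white (255), the
usual convention for binarised micro-CT exports. Component labelling uses
26-connectivity by default (6/18 configurable); the choice matters only for
marginally-touching clusters and is stated everywhere it applies.

All distance computations use an exact integer *squared* Euclidean distance
transform (separable lower-envelope algorithm, numba-compiled, verified
against `scipy.ndimage.distance_transform_edt` by property test). Working
with squared integers makes every probe-radius comparison (`dist >= c/2` ⇔
`4·dist² >= c²`) exact, with no floating-point boundary ambiguity.

## Shrink-wrap accessibility

The probe is a digital ball of diameter *c* voxels: the voxels strictly
within Euclidean distance c/2 of a centre voxel. A centre *fits* where the
distance to the nearest strut voxel is at least c/2 (even diameters are
handled by the same threshold, so no half-integer centre grid is needed).
Fitting centres are labelled; components containing a centre whose ball
touches an entry face (face coordinate < c/2) are retained; the accessible
region is the union of the retained centres' balls. The operation is checked
exhaustively against a brute-force all-ball-placements oracle on random
volumes up to 12³.

Outside the volume counts as open space for fitting (probes enter through
faces), so an *unsealed* VOI admits probes along its cut boundary pores; the
lateral sealing operation (1-voxel solid border on the four x/y faces)
restricts entry to the top/bottom surfaces, and the "open" depth-measurement
mode instead discounts accessible voxels within ceil(c/2) of a lateral face.
A probe larger than the smallest volume dimension returns an empty
accessible set with a warning — such a probe cannot be assessed inside the
VOI at all.

**Nesting.** A family of growing probes is a granulometry: a larger probe
can never reach pore space a smaller one cannot. Digital rasterisation can
violate this by a few boundary voxels between probe sizes of different
parity (measured at ~0.3 percentage points of interconnectivity on a shifted
lattice), so `shrink_wrap_series` intersects each accessible set with its
predecessor's. This restores exact monotonicity of V_c, I(d) and L(d); the
single-probe operation is left exactly as the oracle-checked contract.

**Digital-width caveat.** With voxel-centre ball placement, a straight
channel of even width w passes probes up to exactly c = w, while an odd
width passes up to c = w + 1; on the even-c schedules used throughout
(cluster step 2), the all-or-nothing transition of straight channels sits at
the channel width. Square channels wider than ~6 voxels are traversed fully
but their digital corners fall outside any fitting ball near c ≈ w, so
"fully percolates" is defined by penetration (no blank slice), not
voxel-complete coverage.

## Local thickness

Pore and strut sizes use the maximal-inscribed-sphere definition: the
thickness of a voxel is the diameter of the largest sphere containing it
that fits in the phase. Sphere diameters are measured as twice the
centre-to-nearest-background-voxel distance (2·EDT), the convention of the
standard sphere-fitting morphometry tools; it reads an n-voxel all-pore cube
as n + 1 voxels (one-voxel surface convention), which is the tolerance used
in the corresponding tests. The volume boundary counts as phase surface.

The map is computed as a granulometry: for each candidate squared radius
(descending), centres with at least that clearance are dilated by the same
radius and unassigned voxels take that diameter. Exact computation needs one
distance transform per distinct attained radius; volumes with many distinct
radii (oblique structures) are capped at `max_steps = 64` levels — the
largest 32 kept exactly (the spheres that dominate volume-weighted
statistics), the tail thinned evenly. Small volumes are always exact, which
is what the exhaustive brute-force comparison tests cover. Statistics are
volume-weighted over phase voxels; the histogram reports distinct diameters
with their volume fractions, and D_pore ± 2σ_pore provide the ~95%
largest/smallest-pore estimates used by the planner.

## Synthetic lattices

The generator emulates idealised micro-CT stacks of square-mesh structures:
1-pixel strut lines at physical repeat D_repeat (40–120 µm), simulated pixel
sizes 1.5/3/6 µm, cubic volumes. Non-integer repeats are rasterised at
`round(k·D_repeat/p)` so the long-range average spacing equals the physical
repeat. *Aligned* stacks repeat one slice (straight square channels);
*shifted* stacks move the grid origin one pixel per slice on both in-plane
axes (45° oblique channels, which is why their measured pore size is roughly
D_repeat/1.6 — the perpendicular wall spacing shrinks by ~1/√2).

The noise pipeline per pass: slice-wise 3×3 mean filter (centre included,
edge-replicating boundary), salt-and-pepper inversion of 2.5% of the dark
(<128) and bright (≥128) pixels to 0/255, then a slice-wise Gaussian blur
(σ = 2 px default). All randomness flows from one seed; output is
bit-reproducible. Smoothing and blur are applied per-slice because the
pipeline emulates 2D image-filter passes over a stack; a 3D variant would
couple slices and change the noise character. A blur radius tied to the
stack depth (hundreds of pixels) would homogenise the volume entirely, so
the radius is an explicit parameter rather than a derived quantity.

What the phantoms do *not* emulate: X-ray physics, reconstruction artefacts
(rings, beam hardening), partial-volume gray levels, or the disordered pore
geometry of real scaffolds. Passing the lattice studies shows the
measurement chain is correct on structures with known geometry; it does not
by itself validate accuracy on real, disordered materials.

## Percolation fitting

Penetration depths come from the saved post-shrink-wrap masks: L_top is the
distance from the top to the first entirely blank slice (L_bot symmetric).
Stacks with no blank slice are flagged *full percolation*, stacks blank at
the surface *zero penetration*; both are excluded from the regression by
default — saturated depths carry no information about the transition and
bias the infinite-volume intercept. The fit is OLS of L^(−1/ν) on d with
ν fixed at 0.88 (3D percolation exponent; overridable, never fitted);
d_perc = −intercept/slope. Slope ≤ 0 or fewer than n_data (default 6)
usable points raise a fit error; negative intercepts are returned but
flagged unphysical.

Perfectly regular lattices percolate all-or-nothing (no partial-penetration
band), so no percolation diameter exists for them — the honest outcome, also
surfaced as an error by plateau selection when nothing fits. Graded
penetration requires structural variation along the depth; tests use a
funnel phantom (channels narrowing with depth) whose depth profile has a
closed-form bracket, plus noise-degraded lattices.

## Segmented percolation and plateau selection

Subdivision operates on the *saved* masks (no re-shrink-wrap): crops of side
R_i = round(R₀ − i·R₀/g_sub), centre-anchored at floor((R₀−R_i)/2) or
anchored at the top-left corner, i = 0 … g_sub−1, stopping below 2 px and
skipping duplicate sizes so R_i is strictly decreasing. g_sub defaults
to 20. Per subdivision method and per measurement direction (top/bottom),
fitted diameters are rounded to the nearest multiple of p (half away from
zero), non-positive entries dropped, and the longest run of identical
consecutive values over decreasing R_i selected. Ties break toward the
plateau at larger R_i, since the large-R side precedes the small-ROI
collapse that sets in once sub-ROIs shrink below the pore scale. The
overall stable diameter is the longest plateau across all traces; per-method
means ± sd over the two directions are reported alongside, since systematic
anomalies can affect the two anchors and directions differently.

## Pixel-size planner

Pure closed-form evaluation of the window
(D_pore + 2σ)/(c_max − g_c·n_data) < p < (D_pore − 2σ)/(c_min + g_c·n_data),
with the resolution bound D_fen/c_min selected by an explicit
`fenestrations_relevant` flag (the "object much larger than fenestration"
judgement is qualitative, so it is the caller's). Bounds carry full
precision; display rounding is one decimal. The window is open: boundary
equality of p_experiment counts as infeasible. Infeasible windows are
returned with diagnostics, not raised — an infeasible plan is a result.

## Problem sizes and defaults

The lattice studies regenerate all 15 (pixel size × repeat) combinations per
family at 200³ voxels, which keeps 2.5–30 grid repeats in view at every
pixel size and runs in a few minutes on one CPU; the package-level study
functions expose `n_vox` for larger runs. Cluster schedules default to
2–100 step 2 for synthetic work and 2–30 step 2 is the preset used for real
scans; depth fits default to n_data = 6. Sweep despeckling retains all
components tying at the maximal size per phase, so regular structures with
many identical channels are preserved.

## Known limitations

* Voxel-centre ball placement cannot represent half-integer sphere centres;
  transition widths are resolved to the even-c schedule (one-pixel effects
  on odd widths are intrinsic and documented above).
* Local thickness at `max_steps` below the number of attained radii
  underestimates tail thicknesses by up to one radius bin.
* The open-mode "surface pores only" criterion (lateral-shell discounting)
  is one operationalisation of an informally specified rule and is exposed
  as a mode switch.
* Anisotropic voxels and grayscale (partial-volume) accessibility are out
  of scope.
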