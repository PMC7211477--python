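"""Percolation depths, scaling-law regression, subdivision and plateaus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poreperc import (ClusterRange, FitError, fit_percolation,
                      inject_anomaly, percolation_depths,
                      seal_lateral_faces, segmented_percolation,
                      select_stable_diameter, shrink_wrap,
                      shrink_wrap_series, subdivide_roi, subdivision_sizes)
from poreperc.percolation import (DepthProfile, PercolationFit,
                                  SubdivisionIteration, SubdivisionTrace)

from conftest import funnel_width, make_funnel, passable


def _profile_from_law(d, d_star, L0, nu, full_depth=1e9, p=1.0):
    """DepthProfile with depths generated exactly from L = L0 (d-d*)^-nu."""
    d = np.asarray(d, float)
    L = L0 * (d - d_star) ** -nu
    n = d.size
    false = np.zeros(n, bool)
    return DepthProfile(
        cluster_sizes=np.rint(d / p).astype(int), d_um=d,
        L_top_um=L, L_bot_um=L, full_depth_um=full_depth, pixel_size_um=p,
        full_percolation_top=false, full_percolation_bot=false,
        zero_penetration_top=false, zero_penetration_bot=false,
    )


class TestPercolationDepths:
    def test_funnel_matches_closed_form(self, funnel_series, funnel_sealed):
        # the probe penetrates while the channel stays passable; the
        # accessible column extends past the deepest fitting centre by at
        # most the ball half-width, bracketing L between the construction's
        # closed form and closed form + ceil(c/2) slices
        p = funnel_sealed.pixel_size_um
        prof = percolation_depths(funnel_series)
        full = funnel_sealed.n_slices * p
        for c, L, fp, zp in zip(prof.cluster_sizes, prof.L_top_um,
                                prof.full_percolation_top,
                                prof.zero_penetration_top):
            blank = [z for z in range(funnel_sealed.n_slices)
                     if not passable(c, funnel_width(z))]
            if not blank:
                assert fp and L == full
            elif blank[0] == 0:
                assert zp and L == 0.0
            else:
                lo = blank[0] * p
                assert lo <= L <= lo + ((c + 1) // 2) * p, c

    def test_depths_monotone_non_increasing(self, funnel_series):
        prof = percolation_depths(funnel_series)
        assert (np.diff(prof.L_top_um) <= 0).all()
        assert (np.diff(prof.L_bot_um) <= 0).all()

    def test_bottom_blocked_funnel_zero_penetration(self, funnel_series):
        prof = percolation_depths(funnel_series)
        # bottom slices are the narrowest: large probes cannot enter at all
        big = prof.cluster_sizes >= 13
        assert prof.zero_penetration_top[big].all()
        assert (prof.L_top_um[big] == 0).all()

    def test_open_mode_discounts_lateral_surface_pores(self):
        # unsealed all-pore cube: every voxel accessible from the sides, but
        # open mode ignores the lateral shell, leaving the core column
        from poreperc.volume import from_masks

        vol = from_masks(np.ones((10, 11, 11), bool), 1.0)
        res = [shrink_wrap(vol, 4)]
        sealed_view = percolation_depths(res, mode="sealed")
        open_view = percolation_depths(res, mode="open")
        assert sealed_view.full_percolation_top[0]
        assert open_view.full_percolation_top[0]  # core still percolates
        vol2 = from_masks(np.ones((10, 4, 4), bool), 1.0)
        res2 = [shrink_wrap(vol2, 4)]
        open2 = percolation_depths(res2, mode="open")
        # whole cross-section is lateral shell at this size: nothing counts
        assert open2.zero_penetration_top[0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percolation_depths([])


class TestFitPercolation:
    def test_recovers_parameters_from_exact_law(self):
        prof = _profile_from_law([36, 42, 48, 54, 60], 30.0, 50.0, 0.88)
        fit = fit_percolation(prof, n_data_min=5)
        assert fit.d_perc_um == pytest.approx(30.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.L0_um == pytest.approx(50.0, rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        d_star=st.floats(1.0, 200.0),
        L0=st.floats(0.5, 500.0),
        nu=st.floats(0.2, 3.0),
    )
    def test_parameter_recovery_property(self, d_star, L0, nu):
        d = d_star + np.array([5, 9, 13, 17, 21, 25], float)
        prof = _profile_from_law(d, d_star, L0, nu)
        fit = fit_percolation(prof, nu=nu)
        assert abs(fit.d_perc_um - d_star) <= 1e-6 * max(d_star, 1.0)

    def test_collinear_x_intercept(self):
        # depths manufactured so that L^(-1/nu) = 0.1 (d - 12) exactly
        d = np.array([14.0, 18.0, 25.0, 40.0])
        nu = 0.88
        L = (0.1 * (d - 12.0)) ** -nu
        prof = _profile_from_law(d, 12.0, 0.1 ** -nu, nu)
        assert np.allclose(prof.L_top_um, L)
        fit = fit_percolation(prof, nu=nu, n_data_min=4)
        assert fit.d_perc_um == pytest.approx(12.0)

    def test_too_few_points_rejected(self):
        prof = _profile_from_law([36, 42, 48], 30.0, 50.0, 0.88)
        with pytest.raises(FitError, match="too few"):
            fit_percolation(prof, n_data_min=6)

    def test_increasing_depths_rejected(self):
        prof = _profile_from_law([36, 42, 48, 54], 30.0, 50.0, 0.88)
        prof.L_top_um = prof.L_top_um[::-1].copy()  # increasing L with d
        with pytest.raises(FitError, match="non-decreasing"):
            fit_percolation(prof, n_data_min=4)

    def test_flagged_points_excluded(self):
        prof = _profile_from_law([36, 42, 48, 54, 60, 66, 72], 30.0, 50.0, 0.88)
        prof.full_percolation_top[:2] = True
        prof.zero_penetration_top[-1] = True
        fit = fit_percolation(prof, n_data_min=4)
        assert fit.n_points_used == 4

    def test_negative_intercept_flagged_unphysical(self):
        prof = _profile_from_law([30, 40, 50, 60], -20.0, 50.0, 0.88)
        fit = fit_percolation(prof, n_data_min=4)
        assert fit.d_perc_um == pytest.approx(-20.0, rel=1e-6)
        assert not fit.physical


class TestSubdivision:
    def test_schedule_r0_1000_gsub_20(self):
        sizes = subdivision_sizes(1000, 20)
        assert sizes == [(i, 1000 - 50 * i) for i in range(20)]

    def test_left_crops_contain_origin(self, funnel_series):
        masks = [r.accessible_mask for r in funnel_series[:3]]
        for i, R_i, cropped in subdivide_roi(masks, "left", 6):
            for orig, crop in zip(masks, cropped):
                assert crop.shape[1:] == (R_i, R_i)
                assert np.array_equal(crop, orig[:, :R_i, :R_i])

    def test_even_width_centre_full_size_reproduces_uncropped(self):
        rng = np.random.default_rng(0)
        masks = [rng.random((4, 666, 666)) > 0.5]
        (i0, R0, crops0), *_ = subdivide_roi(masks, "centre", 3)
        assert (i0, R0) == (0, 666)
        assert np.array_equal(crops0[0], masks[0])

    def test_centre_anchor_floor_convention(self):
        masks = [np.ones((2, 11, 11), bool)]
        out = subdivide_roi(masks, "centre", 11)
        for i, R_i, crops in out:
            a = (11 - R_i) // 2
            assert crops[0].shape == (2, R_i, R_i)
        assert [R for _, R, _ in out] == [11, 10, 9, 8, 7, 6, 5, 4, 3, 2]

    def test_gsub_below_two_rejected(self):
        with pytest.raises(ValueError):
            subdivision_sizes(100, 1)


def _trace(values, R=None, method="centre", direction="top"):
    R = R or list(range(100, 100 - 10 * len(values), -10))
    its = []
    for i, (v, r) in enumerate(zip(values, R)):
        fit = None if v is None else PercolationFit(v, 0.88, 1.0, 1.0, 6)
        its.append(SubdivisionIteration(i, r, fit))
    return SubdivisionTrace(method, direction, len(values), its)


class TestStableDiameter:
    def test_enumerated_example_with_negative_filtering(self):
        # rounded sequence [36,36,36,30,-6,30,30] at p=6: the -6 entry is
        # dropped, the longest run is 36 (length 3)
        tr = _trace([36.0, 36.0, 36.0, 30.0, -6.0, 30.0, 30.0])
        st_ = select_stable_diameter([tr], 6.0)
        assert st_.d_perc_stable_um == 36.0
        assert st_.plateau_length == 3

    def test_all_equal(self):
        tr = _trace([12.0, 12.0, 12.0])
        assert select_stable_diameter([tr], 6.0).d_perc_stable_um == 12.0

    def test_rounding_to_pixel_multiples(self):
        tr = _trace([34.3, 35.9, 38.5, 20.0])
        st_ = select_stable_diameter([tr], 6.0)
        # 34.3 -> 36, 35.9 -> 36, 38.5 -> 36 (HALF of 39 rounds up... )
        assert st_.d_perc_stable_um == 36.0
        assert st_.plateau_length == 3

    def test_tie_broken_toward_larger_R(self):
        tr = _trace([30.0, 30.0, 18.0, 18.0])
        st_ = select_stable_diameter([tr], 6.0)
        assert st_.d_perc_stable_um == 30.0
        assert st_.plateau_R_range_px == (100, 90)

    def test_no_positive_values_rejected(self):
        tr = _trace([-6.0, -12.0, None])
        with pytest.raises(ValueError, match="no stable"):
            select_stable_diameter([tr], 6.0)

    def test_deterministic_pure_function(self):
        tr = _trace([36.0, 30.0, 30.0, -6.0, 36.0])
        a = select_stable_diameter([tr], 6.0)
        b = select_stable_diameter([tr], 6.0)
        assert a.d_perc_stable_um == b.d_perc_stable_um == 30.0

    def test_per_method_mean_sd_over_directions(self):
        t1 = _trace([30.0, 30.0, 30.0], direction="top")
        t2 = _trace([18.0, 18.0], direction="bottom")
        st_ = select_stable_diameter([t1, t2], 6.0)
        assert st_.per_method_mean_um["centre"] == pytest.approx(24.0)
        assert st_.per_method_sd_um["centre"] == pytest.approx(6.0)


class TestSegmentedPercolation:
    def test_funnel_stable_plateau_region_ii(self, funnel_sealed, funnel_series):
        stable, traces = segmented_percolation(
            funnel_sealed, ClusterRange(2, 16, 1), g_sub=8,
            entry_faces=("top", "bottom"), n_data_min=6,
            results=funnel_series,
        )
        assert stable.d_perc_stable_um > 0
        assert stable.plateau_length >= 3
        # plateau spans a contiguous range of sub-ROI sizes (Region II)
        lo, hi = stable.plateau_R_range_px[1], stable.plateau_R_range_px[0]
        assert lo < hi <= 72

    def test_method_invariance_on_homogeneous_lattice(self, funnel_sealed,
                                                      funnel_series):
        p = funnel_sealed.pixel_size_um
        stable, _ = segmented_percolation(
            funnel_sealed, ClusterRange(2, 16, 1), g_sub=8,
            entry_faces=("top", "bottom"), n_data_min=6,
            results=funnel_series,
        )
        per = {m: stable.per_method_mean_um[m]
               for m in stable.per_method_mean_um}
        if {"centre", "left"} <= per.keys():
            assert abs(per["centre"] - per["left"]) <= p

    def test_region_iii_collapse_below_pore_size(self, funnel_sealed,
                                                 funnel_series):
        # sub-ROIs smaller than one grid cell cannot carry the fit: the
        # smallest iterations yield no (or non-plateau) diameters
        stable, traces = segmented_percolation(
            funnel_sealed, ClusterRange(2, 16, 1), g_sub=8,
            entry_faces=("top", "bottom"), n_data_min=6,
            results=funnel_series,
        )
        for tr in traces:
            tiny = [it for it in tr.iterations if it.R_px < 12]
            for it in tiny:
                assert it.fit is None or \
                    it.fit.d_perc_um < stable.d_perc_stable_um

    def test_gsub_two_equals_direct_fits(self, funnel_sealed, funnel_series):
        stable, traces = segmented_percolation(
            funnel_sealed, ClusterRange(2, 16, 1), g_sub=2,
            methods=("centre",), entry_faces=("top", "bottom"),
            n_data_min=6, results=funnel_series,
        )
        masks = [r.accessible_mask for r in funnel_series]
        from poreperc.percolation import crop_masks
        from poreperc.accessibility import ShrinkWrapResult

        p = funnel_sealed.pixel_size_um
        for tr in traces:
            assert [it.R_px for it in tr.iterations] == [72, 36]
            for it in tr.iterations:
                cropped = crop_masks(masks, "centre", it.R_px)
                subres = [
                    ShrinkWrapResult(r.cluster_size, p, m, 0.0, 0.0, 0.0)
                    for r, m in zip(funnel_series, cropped)
                ]
                prof = percolation_depths(subres)
                try:
                    direct = fit_percolation(prof, tr.direction, n_data_min=6)
                    assert it.fit is not None
                    assert it.fit.d_perc_um == pytest.approx(direct.d_perc_um)
                except FitError:
                    assert it.fit is None


@pytest.fixture(scope="module")
def anomaly_setup(funnel_sealed, funnel_series):
    wide = inject_anomaly(make_funnel(), 14, "top_right")
    sealed = seal_lateral_faces(wide)
    series = shrink_wrap_series(sealed, ClusterRange(2, 16, 1),
                                ("top", "bottom"))
    return sealed, series, funnel_sealed, funnel_series


class TestAnomalyFixture:
    def test_whole_roi_percolation_inflated_by_corner_channel(
            self, anomaly_setup, funnel_series):
        _, series, _, ref_series = anomaly_setup
        # largest probe that still penetrates the whole ROI
        def max_percolating(results):
            ds = [r.probe_diameter_um for r in results
                  if r.accessible_mask.any()]
            return max(ds) if ds else 0.0

        assert max_percolating(series) > max_percolating(ref_series)

    def test_whole_roi_fit_prevented_but_centre_subdivision_recovers(
            self, anomaly_setup):
        sealed, series, ref_sealed, ref_series = anomaly_setup
        p = sealed.pixel_size_um
        # whole-ROI: the corner channel percolates fully at every probe
        # size it admits, so no partial-penetration points remain
        prof = percolation_depths(series)
        with pytest.raises(FitError):
            fit_percolation(prof, "top", n_data_min=6)
        # reference (anomaly-free) stable diameter
        ref_stable, _ = segmented_percolation(
            ref_sealed, ClusterRange(2, 16, 1), g_sub=8,
            entry_faces=("top", "bottom"), n_data_min=6,
            results=ref_series,
        )
        stable, _ = segmented_percolation(
            sealed, ClusterRange(2, 16, 1), g_sub=8, methods=("centre", "left"),
            entry_faces=("top", "bottom"), n_data_min=6, results=series,
        )
        assert abs(stable.d_perc_stable_um - ref_stable.d_perc_stable_um) <= p

    def test_centre_crop_removes_corner_channel(self, anomaly_setup):
        _, series, _, _ = anomaly_setup
        masks = [r.accessible_mask for r in series]
        # at c=14 only the anomaly is accessible; a centre crop to half
        # size excludes the corner entirely
        c_idx = [r.cluster_size for r in series].index(14)
        assert masks[c_idx].any()
        from poreperc.percolation import crop_masks

        cropped = crop_masks([masks[c_idx]], "centre", 36)[0]
        assert not cropped.any()
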