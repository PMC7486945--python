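"""Density metrics, profile correlation and group tests."""

import numpy as np
import pytest

import coroalign as ca
from coroalign.density_and_stats import clip_polyline_to_box


def straight_graph(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return ca.SkeletonGraph(
        node_ids=np.array([0, 1]),
        node_xyz=np.vstack([a, b]),
        segments=[ca.Segment(0, 0, 1, np.vstack([a, b]))],
    )


def profile(depth, mean):
    n = len(depth)
    return ca.DepthProfile(
        depth=np.asarray(depth, float), mean_deg=np.asarray(mean, float),
        kappa=np.ones(n), u_deg=np.ones(n), n=np.full(n, 10),
    )


class TestVolumeFraction:
    def test_half_filled(self):
        data = np.zeros((4, 4, 4))
        data[:2] = 1
        assert ca.volume_fraction(ca.ImageStack(data, (1, 1, 1))) == 0.5

    def test_empty_mask(self):
        assert ca.volume_fraction(ca.ImageStack(np.zeros((4, 4, 4)), (1, 1, 1))) == 0.0

    def test_empty_roi_raises(self):
        stack = ca.ImageStack(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            ca.volume_fraction(stack, (10.0, 10.0, 10.0, 10.5, 10.5, 10.5))

    def test_rasterized_phantom_matches_analytic_cylinder_volume(self):
        spec = ca.WallPhantomSpec(
            geometry="slab", n_segments=30, extent_um=300.0, thickness_um=200.0,
            kappa=8.0, vessel_radius_um=5.0, seed=4, min_depth_um=20.0,
            surface_spacing_um=4.0,
        )
        ph = ca.make_wall_phantom(spec)
        roi = (0.0, 0.0, 0.0, 300.0, 300.0, 200.0)
        mask = ca.rasterize_mask(ph.graph, 5.0, 2.0, roi)
        vf = ca.volume_fraction(mask)
        length = sum(clip_polyline_to_box(s.points, roi) for s in ph.graph.segments)
        analytic = np.pi * 5.0**2 * length / (300.0 * 300.0 * 200.0)
        assert abs(vf - analytic) / analytic < 0.10


class TestLengthDensity:
    def test_one_mm_segment_in_one_mm3(self):
        g = straight_graph([0, 500, 500], [1000, 500, 500])
        assert ca.length_density(g, (0, 0, 0, 1000, 1000, 1000)) == pytest.approx(1.0)

    def test_half_inside_counts_half(self):
        g = straight_graph([-500, 500, 500], [500, 500, 500])
        assert ca.length_density(g, (0, 0, 0, 1000, 1000, 1000)) == pytest.approx(0.5)

    def test_fully_outside_counts_zero(self):
        g = straight_graph([2000, 2000, 2000], [3000, 2000, 2000])
        assert ca.length_density(g, (0, 0, 0, 1000, 1000, 1000)) == 0.0

    @pytest.mark.parametrize("target", [300.0, 800.0])
    def test_generator_target_density_recovered(self, target):
        spec = ca.WallPhantomSpec(
            geometry="slab", target_length_density_mm2=target, extent_um=400.0,
            thickness_um=300.0, seed=5, min_depth_um=20.0, surface_spacing_um=6.0,
        )
        ph = ca.make_wall_phantom(spec)
        got = ca.length_density(ph.graph, (0, 0, 0, 400, 400, 300))
        assert abs(got - target) / target < 0.05

    def test_translation_invariance(self):
        g = straight_graph([100, 200, 300], [400, 200, 300])
        roi = (0.0, 0.0, 0.0, 500.0, 500.0, 500.0)
        base = ca.length_density(g, roi)
        shift = np.array([70.0, -30.0, 12.0])
        g2 = straight_graph(np.array([100, 200, 300]) + shift, np.array([400, 200, 300]) + shift)
        roi2 = tuple((np.asarray(roi).reshape(2, 3) + shift).ravel())
        assert ca.length_density(g2, roi2) == pytest.approx(base)


class TestCorrelateProfiles:
    def test_self_correlation_is_one(self):
        a = profile(np.arange(10.0), np.linspace(-40, 79, 10))
        assert ca.correlate_profiles(a, a).rho == pytest.approx(1.0)

    def test_mirrored_profile_is_minus_one(self):
        d = np.arange(10.0)
        a = profile(d, np.linspace(-40, 79, 10))
        b = profile(d, -np.linspace(-40, 79, 10))
        assert ca.correlate_profiles(a, b).rho == pytest.approx(-1.0)

    def test_constant_offset_still_perfect(self):
        d = np.arange(10.0)
        a = profile(d, np.linspace(-40, 60, 10))
        b = profile(d, np.linspace(-40, 60, 10) + 7.5)
        assert ca.correlate_profiles(a, b).rho == pytest.approx(1.0)

    def test_wrap_through_90_is_unwrapped(self):
        # a profile climbing 0..170 degrees folds to (-90, 90] with a jump;
        # unwrapping must restore the perfect correlation
        raw = np.linspace(0.0, 170.0, 18)
        folded = np.asarray(ca.fold_axial_deg(raw))
        a = profile(np.arange(18.0), folded)
        b = profile(np.arange(18.0), raw)
        assert ca.correlate_profiles(a, b).rho == pytest.approx(1.0)

    def test_non_overlapping_ranges_raise(self):
        a = profile([0.0, 1.0, 2.0], [0, 1, 2])
        b = profile([10.0, 11.0], [0, 1])
        with pytest.raises(ValueError):
            ca.correlate_profiles(a, b)

    def test_constant_series_flagged(self):
        a = profile(np.arange(5.0), np.zeros(5))
        b = profile(np.arange(5.0), np.arange(5.0))
        res = ca.correlate_profiles(a, b)
        assert res.constant_input and np.isnan(res.rho)

    def test_coaligned_phantoms_strongly_correlated(self):
        # vessel and nuclei phantoms sharing one ground-truth orientation
        # function, each with independent kappa=8 dispersion
        shared = lambda d_um: -30.0 + 110.0 * np.asarray(d_um, float) / 550.0
        vspec = ca.WallPhantomSpec(
            geometry="slab", n_segments=1200, kappa=8.0, seed=11,
            surface_spacing_um=4.0,
            mean_profile=lambda fr: shared(15.0 + np.asarray(fr) * (550.0 - 15.0)),
        )
        ph = ca.make_wall_phantom(vspec)
        v_ab = np.asarray(ph.base_um) - np.asarray(ph.apex_um)
        vecs, _ = ca.analyze_segments(ph.graph, ph.surface, v_ab / np.linalg.norm(v_ab))
        vprof = ca.depth_profile(
            np.array([v.projection_deg for v in vecs]),
            np.array([v.depth_um for v in vecs]),
        )
        nspec = ca.NucleiPhantomSpec(
            seed=12, kappa=8.0, n_slices=24, slice_spacing_um=550.0 / 23.0,
            mean_profile=lambda fr: shared(np.asarray(fr) * 550.0),
        )
        stack, _ = ca.make_nuclei_stack(nspec)
        nprof = ca.nuclei_depth_profile(stack)
        assert ca.correlate_profiles(vprof, nprof).rho >= 0.95


class TestCompareGroups:
    def test_identical_groups(self):
        res = ca.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_pvalue == pytest.approx(1.0)

    def test_separated_groups(self):
        res = ca.compare_groups([0.0, 0.0, 0.0, 0.0], [10.0, 10.0, 10.0, 10.0001])
        assert res.t_pvalue < 1e-6

    def test_welch_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        res = ca.compare_groups(x, y)
        se = np.sqrt(np.var(x, ddof=1) / 4 + np.var(y, ddof=1) / 4)
        assert res.t_statistic == pytest.approx((x.mean() - y.mean()) / se)

    def test_zero_variance_both_degenerate(self):
        res = ca.compare_groups([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = sum(
            ca.compare_groups(rng.normal(size=4), rng.normal(size=4)).t_pvalue < 0.05
            for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) <= 0.02
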