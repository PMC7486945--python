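"""Helical/projection angles and depth-resolved vessel summaries."""

import numpy as np
import pytest

import coroalign as ca
from coroalign.vessel_orientation import ExcludedSegmentError

from conftest import axes_frame


class TestHelicalAngle:
    def test_along_g2_is_plus_90(self):
        f = axes_frame()
        assert ca.helical_angle(f.g2, f) == pytest.approx(90.0)

    def test_along_g3_is_circumferential_zero(self):
        f = axes_frame()
        assert ca.helical_angle(f.g3, f) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "combo, expected",
        [((1.0, 1.0), 45.0), ((1.0, -1.0), -45.0), ((np.sqrt(3), 1.0), 30.0)],
    )
    def test_in_plane_combinations(self, combo, expected):
        f = axes_frame()
        c3, c2 = combo
        v = c3 * f.g3 + c2 * f.g2
        assert ca.helical_angle(v, f) == pytest.approx(expected, abs=1e-9)

    def test_any_vector_in_g1_g3_plane_is_zero(self):
        f = axes_frame()
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.normal(size=2)
            if abs(a) + abs(b) < 1e-6:
                continue
            assert ca.helical_angle(a * f.g1 + b * f.g3, f) == pytest.approx(0.0, abs=1e-9)

    def test_direction_reversal_invariant(self):
        # undirected segments: the hemisphere convention makes the helical
        # angle identical, not just axially equivalent, under reversal
        f = axes_frame()
        rng = np.random.default_rng(2)
        for _ in range(10):
            v = rng.normal(size=3)
            assert ca.helical_angle(-v, f) == pytest.approx(
                ca.helical_angle(v, f), abs=1e-12
            )

    def test_zero_vector_excluded(self):
        with pytest.raises(ExcludedSegmentError):
            ca.helical_angle(np.zeros(3), axes_frame())


class TestProjectionAngle:
    def test_along_g3_is_zero(self):
        f = axes_frame()
        assert ca.projection_angle(f.g3, f) == pytest.approx(0.0)

    def test_along_g2_is_90(self):
        f = axes_frame()
        assert ca.projection_angle(f.g2, f) == pytest.approx(90.0)

    def test_radial_component_removed(self):
        f = axes_frame()
        v = f.g2 + f.g3 + 5.0 * f.g1
        assert ca.projection_angle(v, f) == pytest.approx(45.0, abs=1e-9)

    def test_radial_vector_excluded(self):
        f = axes_frame()
        with pytest.raises(ExcludedSegmentError):
            ca.projection_angle(f.g1 * 3.0, f)

    def test_equals_helical_for_in_plane_vectors(self, slab_vectors):
        vectors, _ = slab_vectors
        for v in vectors:
            assert v.projection_deg == pytest.approx(v.helical_deg, abs=0.5)


class TestSlabRecovery:
    def test_per_segment_angles_match_generator(self, slab_phantom, slab_vectors):
        vectors, counts = slab_vectors
        assert counts["included"] == slab_phantom.graph.n_segments
        truth = slab_phantom.truth.set_index("segment_id")
        for v in vectors:
            err = ca.fold_axial_deg(v.helical_deg - truth.angle_deg[v.segment_id])
            assert abs(float(err)) < 0.5
            assert v.depth_um == pytest.approx(truth.depth_um[v.segment_id], abs=0.5)


class TestDepthProfile:
    def test_constant_angles_give_constant_profile(self):
        prof = ca.depth_profile(
            np.full(100, 30.0), np.linspace(0, 100, 100), min_bin_count=5
        )
        ok = prof.valid()
        assert ok.any()
        assert np.allclose(prof.mean_deg[ok], 30.0, atol=1e-6)
        # zero-dispersion bins drive the fit to its upper concentration bound
        assert np.all(prof.kappa[ok] > 100.0)

    def test_two_disjoint_strata(self):
        angles = np.concatenate([np.full(50, -20.0), np.full(50, 70.0)])
        depths = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)])
        prof = ca.depth_profile(angles, depths, half_width_um=15.0, min_bin_count=5)
        shallow = prof.depth <= 25.0
        deep = prof.depth >= 185.0
        assert np.allclose(prof.mean_deg[shallow & prof.valid()], -20.0, atol=1e-6)
        assert np.allclose(prof.mean_deg[deep & prof.valid()], 70.0, atol=1e-6)
        middle = ~shallow & ~deep
        assert not prof.valid()[middle].any()  # empty windows flagged, not filled

    def test_small_bins_flagged_not_interpolated(self):
        prof = ca.depth_profile(np.array([10.0]), np.array([50.0]), min_bin_count=10)
        assert not prof.valid().any()
        assert prof.n[0] == 1

    def test_phantom_profile_tracks_realized_truth(self, slab_phantom, slab_vectors):
        vectors, _ = slab_vectors
        angles = np.array([v.helical_deg for v in vectors])
        depths = np.array([v.depth_um for v in vectors])
        prof = ca.depth_profile(angles, depths, half_width_um=15.0)
        truth = slab_phantom.truth
        checked = 0
        for c, m, n in zip(prof.depth, prof.mean_deg, prof.n):
            if n < 30 or not np.isfinite(m):
                continue
            inside = np.abs(truth.depth_um.values - c) <= 15.0
            mu, _ = ca.axial_mean(ca.AngularSample(truth.angle_deg.values[inside]))
            assert abs(float(ca.fold_axial_deg(m - mu))) < 5.0
            checked += 1
        assert checked >= 5


class TestLocalAngleField:
    def _vector(self, seg_id, xyz, angle):
        return ca.VesselVector(
            segment_id=seg_id, v_v=np.array([1.0, 0, 0]), depth_um=1.0,
            length_um=1.0, helical_deg=angle, projection_deg=angle,
            midpoint_um=np.asarray(xyz, float),
        )

    def test_single_segment_is_its_own_mean(self):
        field = ca.local_angle_field([self._vector(0, (0, 0, 0), 33.0)])
        assert field.mean_deg[0] == pytest.approx(33.0)

    def test_uniform_angles_give_constant_field(self):
        rng = np.random.default_rng(5)
        vecs = [self._vector(i, rng.uniform(0, 500, 3), 12.0) for i in range(40)]
        field = ca.local_angle_field(vecs)
        assert np.allclose(field.mean_deg, 12.0, atol=1e-9)

    def test_two_layer_transition_confined_to_window(self):
        # two z layers 400 um apart, window extent 175 um in z
        vecs = [self._vector(i, (i * 10.0, 0.0, 0.0), -20.0) for i in range(20)]
        vecs += [self._vector(100 + i, (i * 10.0, 0.0, 400.0), 70.0) for i in range(20)]
        field = ca.local_angle_field(vecs, window_um=(1000.0, 1000.0, 175.0))
        assert np.allclose(field.mean_deg[:20], -20.0, atol=1e-9)
        assert np.allclose(field.mean_deg[20:], 70.0, atol=1e-9)


class TestNormalizeDepth:
    def test_affine_endpoints(self):
        prof = ca.DepthProfile(
            depth=[100.0, 350.0, 600.0], mean_deg=[0, 10, 20],
            kappa=[1, 1, 1], u_deg=[1, 1, 1], n=[5, 5, 5],
        )
        out = ca.normalize_depth(prof, (100.0, 600.0))
        assert np.allclose(out.depth, [0.0, 0.5, 1.0])
        assert np.allclose(out.mean_deg, prof.mean_deg)
        assert out.normalized

    def test_identity_on_unit_bounds(self):
        prof = ca.DepthProfile(
            depth=[0.0, 0.5, 1.0], mean_deg=[0, 1, 2],
            kappa=[1, 1, 1], u_deg=[1, 1, 1], n=[5, 5, 5], normalized=True,
        )
        out = ca.normalize_depth(prof, (0.0, 1.0))
        assert np.allclose(out.depth, prof.depth)

    def test_zero_thickness_raises(self):
        prof = ca.DepthProfile(
            depth=[1.0, 2.0], mean_deg=[0, 0], kappa=[1, 1], u_deg=[1, 1], n=[5, 5]
        )
        with pytest.raises(ValueError):
            ca.normalize_depth(prof, (10.0, 10.0))

    def test_thin_and_thick_walls_overlay_when_normalized(self):
        # same transmural organization at two wall thicknesses collapses
        # onto one normalized profile
        profiles = []
        for thickness, seed in ((550.0, 21), (900.0, 22)):
            spec = ca.WallPhantomSpec(
                geometry="slab", n_segments=600, extent_um=400.0,
                thickness_um=thickness, kappa=50.0, seed=seed,
                min_depth_um=15.0, surface_spacing_um=4.0,
            )
            ph = ca.make_wall_phantom(spec)
            v_ab = np.asarray(ph.base_um) - np.asarray(ph.apex_um)
            vecs, _ = ca.analyze_segments(ph.graph, ph.surface, v_ab / np.linalg.norm(v_ab))
            prof = ca.depth_profile(
                np.array([v.helical_deg for v in vecs]),
                np.array([v.depth_um for v in vecs]),
            )
            d = np.array([v.depth_um for v in vecs])
            profiles.append(ca.normalize_depth(prof, (d.min(), d.max())))
        a, b = profiles
        grid = np.linspace(0.05, 0.95, 20)
        ia = np.interp(grid, a.depth[a.valid()], a.mean_deg[a.valid()])
        ib = np.interp(grid, b.depth[b.valid()], b.mean_deg[b.valid()])
        assert np.max(np.abs(ia - ib)) < 8.0
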