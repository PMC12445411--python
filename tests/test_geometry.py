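"""Layer decomposition: centre, rays, interpolation, midline, layer masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

import transperf as tp
from transperf.geometry import GeometryError

from conftest import offset_centers


# ---------------------------------------------------------------------------
# blood-pool centre
# ---------------------------------------------------------------------------

class TestBloodPoolCenter:
    def test_circle_centroid_is_its_center(self):
        ctr = tp.annulus_contours(tp.PhantomSpec(center=(50.0, 50.0)))
        c = tp.compute_blood_pool_center(ctr)
        assert np.allclose(c, [50.0, 50.0], atol=1e-9)

    def test_square_centroid(self):
        square = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        epi = Polygon([(-10, -10), (20, -10), (20, 20), (-10, 20)])
        c = tp.compute_blood_pool_center(tp.ContourSet(square, epi, (20, 5)))
        assert np.allclose(c, [5.0, 5.0])

    def test_crescent_matches_point_sampling_oracle(self):
        # non-convex endo: circle with a circular bite taken out of one side
        endo = Point(50, 50).buffer(10, quad_segs=90).difference(
            Point(58, 50).buffer(5, quad_segs=90))
        epi = Point(50, 50).buffer(25, quad_segs=90)
        c = tp.compute_blood_pool_center(tp.ContourSet(endo, epi, (75, 50)))
        # brute-force centroid: dense grid of points inside the polygon
        xs = np.arange(38, 62, 0.02)
        X, Y = np.meshgrid(xs, xs)
        import shapely
        inside = shapely.contains_xy(endo, X.ravel(), Y.ravel())
        oracle = np.array([X.ravel()[inside].mean(), Y.ravel()[inside].mean()])
        assert np.linalg.norm(c - oracle) < 0.1
        assert endo.contains(Point(*c))

    def test_degenerate_polygon_rejected(self):
        # a zero-area endo contour never survives ContourSet validation
        with pytest.raises(GeometryError):
            tp.ContourSet(Polygon([(0, 0), (1, 0), (2, 0)]),
                          Point(1, 0).buffer(5), (6, 0))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

class TestInterpolateMap:
    def test_identity_resampling(self):
        pmap, _, _ = tp.make_phantom(tp.PhantomSpec(noise_sd=0.2, seed=3))
        out = tp.interpolate_map(pmap, 1.0)
        assert out.values.shape == pmap.values.shape
        np.testing.assert_allclose(out.values, pmap.values, equal_nan=True)

    @pytest.mark.parametrize("spacing", [0.5, 1.0, 2.0])
    def test_constant_map_stays_constant(self, spacing):
        pmap = tp.PerfusionMap(np.full((40, 40), 1.7), 2.0, "mid", "rest")
        out = tp.interpolate_map(pmap, spacing)
        np.testing.assert_allclose(out.values, 1.7)

    def test_bilinear_exact_for_affine_field(self):
        vals = np.fromfunction(
            lambda r, c: 0.3 * ((c + 0.5) * 2.0) + 0.1 * ((r + 0.5) * 2.0) + 1.0,
            (40, 40))
        out = tp.interpolate_map(tp.PerfusionMap(vals, 2.0, "mid", "rest"), 1.0)
        X, Y = out.pixel_centers()
        expected = 0.3 * X + 0.1 * Y + 1.0
        # interior only: the edge row/column extrapolates beyond the source
        # pixel-centre lattice
        np.testing.assert_allclose(out.values[2:-2, 2:-2],
                                   expected[2:-2, 2:-2], atol=1e-12)

    def test_background_does_not_bleed_into_myocardium(self):
        pmap, ctr, _ = tp.make_phantom(tp.PhantomSpec(
            profile="uniform", endo_value=2.0, pixel_spacing=2.0,
            grid_shape=(64, 64)))
        out = tp.interpolate_map(pmap, 0.5)
        myo = tp.assign_layers(out, ctr).myocardium
        inner = myo & np.isfinite(out.values)
        assert np.allclose(out.values[inner], 2.0)

    def test_oversized_target_spacing_rejected(self):
        pmap = tp.PerfusionMap(np.ones((10, 10)), 1.0, "mid", "rest")
        with pytest.raises(ValueError, match="extent"):
            tp.interpolate_map(pmap, 50.0)


# ---------------------------------------------------------------------------
# rays and midline
# ---------------------------------------------------------------------------

class TestRays:
    def test_360_rays_are_one_degree_apart(self):
        rays = tp.cast_rays(360)
        ang = np.degrees(np.arctan2(rays[:, 1], rays[:, 0]))
        step = np.diff(np.unwrap(np.radians(ang)))
        assert np.allclose(np.degrees(step), 1.0, atol=1e-9)

    def test_four_rays_are_orthogonal(self):
        rays = tp.cast_rays(8)[::2]
        for i in range(4):
            assert abs(np.dot(rays[i], rays[(i + 1) % 4])) < 1e-12

    @pytest.mark.parametrize("n", [8, 9, 360, 1000])
    def test_uniform_directions_sum_to_zero(self, n):
        assert np.linalg.norm(tp.cast_rays(n).sum(axis=0)) < 1e-9

    def test_too_few_rays_rejected(self):
        with pytest.raises(ValueError):
            tp.cast_rays(4)


class TestMidline:
    def test_concentric_circles_give_mid_radius(self):
        ctr = tp.annulus_contours(tp.PhantomSpec(endo_radius=20, epi_radius=30))
        mid = tp.compute_midline(ctr)
        r = np.hypot(mid[:, 0] - 64, mid[:, 1] - 64)
        assert mid.shape == (360, 2)
        assert np.all(np.abs(r - 25.0) < 5e-3)

    def test_confocal_ellipses_match_ray_march_oracle(self):
        spec = tp.PhantomSpec(endo_radius=(20, 15), epi_radius=(30, 25))
        ctr = tp.annulus_contours(spec)
        mid = tp.compute_midline(ctr)
        center = tp.compute_blood_pool_center(ctr)
        rays = tp.cast_rays(360)

        def march_crossing(d, rx, ry):
            # brute-force scan along the ray at 0.01 mm for the sign change of
            # the ellipse implicit function
            t = np.arange(0.0, 45.0, 0.01)
            px = center[0] + t * d[0] - spec.center[0]
            py = center[1] + t * d[1] - spec.center[1]
            f = (px / rx) ** 2 + (py / ry) ** 2 - 1.0
            k = int(np.argmax(f > 0))
            return center + t[k] * d

        for i in range(360):
            p_endo = march_crossing(rays[i], 20, 15)
            p_epi = march_crossing(rays[i], 30, 25)
            oracle = 0.5 * (p_endo + p_epi)
            assert np.linalg.norm(mid[i] - oracle) < 0.05, f"ray {i}"

    def test_translation_equivariance(self):
        ctr = tp.annulus_contours(tp.PhantomSpec(endo_radius=(20, 15),
                                                 epi_radius=(30, 25)))
        mid = tp.compute_midline(ctr, n_rays=90)
        shifted = tp.compute_midline(ctr.translated(3.25, -1.5), n_rays=90)
        np.testing.assert_allclose(shifted, mid + [3.25, -1.5], atol=1e-9)

    def test_non_star_contour_rejected_with_ray_angle(self):
        # epi with an overhanging hook: some rays cross its boundary 3 times
        hook = unary_union([
            Point(64, 64).buffer(28, quad_segs=90),
            box(88, 60, 110, 68), box(102, 68, 110, 96), box(80, 88, 110, 96)])
        endo = Point(50, 64).buffer(6, quad_segs=90)
        with pytest.raises(GeometryError, match="deg"):
            tp.compute_midline(tp.ContourSet(endo, hook, (64, 92)))


# ---------------------------------------------------------------------------
# layer assignment
# ---------------------------------------------------------------------------

class TestAssignLayers:
    def test_radial_ordering_of_layers(self, step_phantom_05):
        spec, pmap, _, _, masks = step_phantom_05
        X, Y = pmap.pixel_centers()
        r = np.hypot(X - spec.center[0], Y - spec.center[1])
        assert masks.endo_layer[np.abs(r - 22.0) < 0.2].all()
        assert masks.epi_layer[np.abs(r - 28.0) < 0.2].all()

    def test_half_annulus_area_ratio(self):
        # analytic half-annulus areas for r 20/25/30 are 225*pi and 275*pi
        pmap, ctr, _ = tp.make_phantom(tp.PhantomSpec(
            pixel_spacing=0.25, grid_shape=(512, 512)))
        masks = tp.assign_layers(pmap, ctr)
        ratio = masks.endo_layer.sum() / masks.epi_layer.sum()
        assert abs(ratio - 225 / 275) / (225 / 275) < 0.01

    def test_partition_is_exact(self, step_phantom_05):
        _, _, _, _, masks = step_phantom_05
        assert not (masks.endo_layer & masks.epi_layer).any()
        assert ((masks.endo_layer | masks.epi_layer) == masks.myocardium).all()
        assert (masks.endo_layer.sum() + masks.epi_layer.sum()
                == masks.myocardium.sum())

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        r_endo=st.floats(8, 18), wall=st.floats(4, 12),
        ecc=st.floats(0.7, 1.0), spacing=st.sampled_from([0.5, 1.0, 2.0]),
        dx=st.floats(-2, 2), dy=st.floats(-2, 2))
    def test_partition_property_randomized(self, r_endo, wall, ecc, spacing,
                                           dx, dy):
        """Endo and epi layers partition the myocardium for arbitrary valid
        annuli (circles and ellipses, off-centre, any spacing)."""
        r_epi = r_endo + wall
        n = int(np.ceil(2 * (r_epi + 4) / spacing))
        c = (n * spacing / 2 + dx, n * spacing / 2 + dy)
        spec = tp.PhantomSpec(
            grid_shape=(n, n), pixel_spacing=spacing, center=c,
            endo_radius=(r_endo, r_endo * ecc), epi_radius=(r_epi, r_epi * ecc))
        pmap, ctr, _ = tp.make_phantom(spec)
        masks = tp.assign_layers(pmap, ctr, n_rays=90)
        assert not (masks.endo_layer & masks.epi_layer).any()
        assert ((masks.endo_layer | masks.epi_layer) == masks.myocardium).all()

    def test_oracle_equivalence_on_concentric_circles(self, step_phantom_05):
        """Midline-polygon assignment agrees with radial-distance
        classification for > 99.5% of myocardial pixels at 0.5 mm."""
        spec, pmap, _, _, masks = step_phantom_05
        X, Y = pmap.pixel_centers()
        r = np.hypot(X - spec.center[0], Y - spec.center[1])
        oracle_endo = masks.myocardium & (r < 25.0)
        agreement = (masks.endo_layer == oracle_endo)[masks.myocardium].mean()
        assert agreement > 0.995

    def test_rotation_robustness(self):
        """Rotating map and contours by 90 degrees leaves layer means
        unchanged (elliptical annulus with seeded noise)."""
        spec = tp.PhantomSpec(endo_radius=(20, 14), epi_radius=(30, 22),
                              profile="linear", endo_value=1.4, epi_value=1.0,
                              noise_sd=0.1, seed=11)
        pmap, ctr, _ = tp.make_phantom(spec)
        masks = tp.assign_layers(pmap, ctr)
        means = [tp.region_mean_mbf(pmap, masks.endo_layer),
                 tp.region_mean_mbf(pmap, masks.epi_layer)]

        # np.rot90 realises the rigid rotation (x, y) -> (y, S - x) of the
        # pixel lattice; rotate the contours by -90 about the grid centre
        import shapely.affinity as aff
        S = spec.grid_shape[0] * spec.pixel_spacing
        rot_vals = np.rot90(pmap.values)
        rot_map = tp.PerfusionMap(rot_vals, spec.pixel_spacing, "mid", "stress")
        origin = (S / 2, S / 2)
        rv = aff.rotate(Point(*ctr.rv_insertion), -90, origin=origin)
        rot_ctr = tp.ContourSet(aff.rotate(ctr.endo, -90, origin=origin),
                                aff.rotate(ctr.epi, -90, origin=origin),
                                (rv.x, rv.y))
        rot_masks = tp.assign_layers(rot_map, rot_ctr)
        rot_means = [tp.region_mean_mbf(rot_map, rot_masks.endo_layer),
                     tp.region_mean_mbf(rot_map, rot_masks.epi_layer)]
        np.testing.assert_allclose(rot_means, means, rtol=1e-4)

    def test_resolution_convergence_through_pipeline(self):
        """Layer-mean error vs analytic truth decreases 2.0 -> 1.0 -> 0.5 mm
        (averaged over sub-pixel grid offsets to remove alignment aliasing)."""
        centers = offset_centers(8, 0, 72)
        errs = []
        for sp in (2.0, 1.0, 0.5):
            per = []
            for c in centers:
                n = int(round(72 / sp))
                pmap, ctr, gt = tp.make_phantom(tp.PhantomSpec(
                    profile="linear", endo_value=1.2, epi_value=1.0,
                    pixel_spacing=sp, grid_shape=(n, n), center=c))
                masks = tp.assign_layers(pmap, ctr)
                per.append(
                    abs(tp.region_mean_mbf(pmap, masks.endo_layer)
                        - gt["endo_mean"])
                    + abs(tp.region_mean_mbf(pmap, masks.epi_layer)
                          - gt["epi_mean"]))
            errs.append(np.mean(per))
        assert errs[0] > errs[1] > errs[2]

    def test_empty_myocardium_rejected(self):
        pmap = tp.PerfusionMap(np.ones((20, 20)), 1.0, "mid", "rest")
        ctr = tp.annulus_contours(tp.PhantomSpec(
            grid_shape=(200, 200), center=(100, 100)))
        with pytest.raises(GeometryError, match="empty"):
            tp.assign_layers(pmap, ctr, n_rays=90)


class TestContourValidation:
    def test_endo_outside_epi_rejected(self):
        endo = Point(50, 50).buffer(30)
        epi = Point(50, 50).buffer(20)
        with pytest.raises(GeometryError):
            tp.ContourSet(endo, epi, (70, 50))

    def test_map_invariants(self):
        with pytest.raises(ValueError):
            tp.PerfusionMap(np.ones((4, 4)), -1.0, "mid", "rest")
        with pytest.raises(ValueError):
            tp.PerfusionMap(-np.ones((4, 4)), 1.0, "mid", "rest")
        with pytest.raises(ValueError):
            tp.PerfusionMap(np.ones((4, 4)), 1.0, "midd", "rest")
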