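import numpy as np
import pytest

from carotidfr.lumen import (
    LumenContour,
    diameter_series,
    effective_diameter,
    extract_contour,
    fwhm_crossings,
    polygon_area,
)
from carotidfr.recon import Image4D
from carotidfr.synthdata import render_phantom


def _movie(spec, diameters):
    frames = [render_phantom(spec, d) for d in diameters]
    return Image4D(
        data=np.stack(frames, axis=-1).astype(complex),
        voxel_mm=spec.voxel_mm,
        bin_width_ms=80.0,
    )


class TestFwhmCrossings:
    def test_plateau_profile(self):
        """Half-range crossings of (0,0,10,10,10,0,0) at unit spacing:
        the symmetric profile gives 1.5 and 4.5 (width 3.0)."""
        left, right = fwhm_crossings(np.array([0, 0, 10, 10, 10, 0, 0.0]), np.arange(7.0))
        assert (left, right) == (1.5, 4.5)

    def test_triangular_width_is_half_base(self):
        prof = np.array([0.0, 5.0, 10.0, 5.0, 0.0])
        left, right = fwhm_crossings(prof, np.arange(5.0))
        assert right - left == pytest.approx(2.0)  # base 4, FWHM = half

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            fwhm_crossings(np.ones(7), np.arange(7.0))

    def test_missing_crossing_rejected(self):
        with pytest.raises(ValueError, match="right"):
            fwhm_crossings(np.array([0.0, 2.0, 5.0, 8.0, 10.0]), np.arange(5.0))


class TestExtractContour:
    def test_analytic_disk_radii(self, phantom_spec):
        img = render_phantom(phantom_spec, 6.0)[:, :, 32]
        c = extract_contour(img, phantom_spec.vessel_centers_mm[0], voxel_mm=0.6)
        radii = np.linalg.norm(c.vertices_mm - c.center_mm, axis=1)
        np.testing.assert_allclose(radii, 3.0, atol=0.3)

    def test_off_center_seed_converges(self, phantom_spec):
        """Any seed inside the lumen converges to the same centroid and
        the same measured area (fixed point of the centroid map)."""
        from carotidfr.lumen import effective_diameter, polygon_area

        img = render_phantom(phantom_spec, 6.0)[:, :, 32]
        cx, cy = phantom_spec.vessel_centers_mm[0]
        a = extract_contour(img, (cx, cy), voxel_mm=0.6)
        b = extract_contour(img, (cx + 1.5, cy - 1.0), voxel_mm=0.6)
        np.testing.assert_allclose(a.center_mm, b.center_mm, atol=0.12)
        assert effective_diameter(polygon_area(b)) == pytest.approx(
            effective_diameter(polygon_area(a)), abs=0.05
        )

    def test_vertex_count(self, phantom_spec):
        img = render_phantom(phantom_spec, 6.0)[:, :, 32]
        c = extract_contour(img, phantom_spec.vessel_centers_mm[0], voxel_mm=0.6,
                            n_rays=64)
        assert c.vertices_mm.shape == (64, 2)

    def test_failure_reports_angles(self, phantom_spec):
        img = np.ones((64, 64))
        with pytest.raises(ValueError, match="ray"):
            extract_contour(img, phantom_spec.vessel_centers_mm[0], voxel_mm=0.6)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])) == 1.0

    def test_triangle(self):
        assert polygon_area(np.array([[0, 0], [1, 0], [0, 1.0]])) == 0.5

    def test_regular_64gon_closed_form(self):
        n, r = 64, 3.0
        ang = 2 * np.pi * np.arange(n) / n
        poly = r * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        want = 0.5 * n * r**2 * np.sin(2 * np.pi / n)
        assert polygon_area(poly) == pytest.approx(want, abs=1e-9)

    def test_matches_shapely_on_star_polygons(self, rng):
        from shapely.geometry import Polygon

        for _ in range(20):
            n = int(rng.integers(8, 40))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(1.0, 4.0, n)
            poly = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
            assert polygon_area(poly) == pytest.approx(Polygon(poly).area, rel=1e-12)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            polygon_area(np.array([[0, 0], [1, 1.0]]))
        with pytest.raises(ValueError):
            LumenContour(vertices_mm=np.zeros((5, 2)), center_mm=np.zeros(2))


class TestEffectiveDiameter:
    def test_unit_circle_area(self):
        assert effective_diameter(np.pi) == pytest.approx(2.0, abs=1e-15)

    def test_closed_form_value(self):
        assert effective_diameter(28.2477) == pytest.approx(5.997, abs=1e-3)

    @pytest.mark.parametrize("r", [0.7, 1.3, 2.9])
    def test_circle_identity(self, r):
        assert effective_diameter(np.pi * r**2) == pytest.approx(2 * r, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            effective_diameter(0.0)


class TestDiameterSeries:
    def test_static_movie_has_equal_extrema(self, phantom_spec):
        movie = _movie(phantom_spec, [5.8, 5.8, 5.8])
        s = diameter_series(movie, phantom_spec.vessel_centers_mm[0])
        assert s.d_s == s.d_d

    def test_recovers_waveform_extrema_within_half_voxel(self, phantom_spec):
        movie = _movie(phantom_spec, [5.5, 6.0, 6.4, 6.0])
        for vessel, center in zip(("LC", "RC"), phantom_spec.vessel_centers_mm):
            s = diameter_series(movie, center, vessel=vessel)
            assert s.d_s == pytest.approx(6.4, abs=0.3)
            assert s.d_d == pytest.approx(5.5, abs=0.3)

    def test_identical_slices_equal_single_slice(self, phantom_spec):
        movie = _movie(phantom_spec, [5.5, 6.4])
        c = phantom_spec.vessel_centers_mm[0]
        three = diameter_series(movie, c, slice_indices=(30, 32, 34))
        one = diameter_series(movie, c, slice_indices=(32,))
        assert three.d_s == pytest.approx(one.d_s, abs=1e-12)
        assert three.d_d == pytest.approx(one.d_d, abs=1e-12)

    def test_invariant_to_intensity_scaling(self, phantom_spec):
        movie = _movie(phantom_spec, [5.5, 6.4])
        scaled = Image4D(data=movie.data * 7.3, voxel_mm=0.6, bin_width_ms=80.0)
        c = phantom_spec.vessel_centers_mm[0]
        a = diameter_series(movie, c)
        b = diameter_series(scaled, c)
        np.testing.assert_allclose(a.diameters_mm, b.diameters_mm, atol=1e-12)

    def test_invariant_to_whole_voxel_translation(self, phantom_spec):
        movie = _movie(phantom_spec, [5.5, 6.4])
        shifted = Image4D(
            data=np.roll(movie.data, 3, axis=0), voxel_mm=0.6, bin_width_ms=80.0
        )
        cx, cy = phantom_spec.vessel_centers_mm[0]
        a = diameter_series(movie, (cx, cy))
        b = diameter_series(shifted, (cx + 3 * 0.6, cy))
        np.testing.assert_allclose(a.diameters_mm, b.diameters_mm, atol=1e-9)

    def test_monotone_under_dilation(self, phantom_spec):
        c = phantom_spec.vessel_centers_mm[0]
        est = []
        for d in (5.0, 5.5, 6.0, 6.5):
            movie = _movie(phantom_spec, [d, d])
            est.append(diameter_series(movie, c).d_s)
        assert np.all(np.diff(est) > 0)
        np.testing.assert_allclose(est, (5.0, 5.5, 6.0, 6.5), atol=0.3)

    def test_contour_failure_identifies_slice_and_phase(self, phantom_spec):
        movie = _movie(phantom_spec, [5.5, 6.4])
        movie.data[:, :, 34, 1] = 1.0  # destroy one slice in one phase
        with pytest.raises(ValueError, match=r"slice 34, phase 1"):
            diameter_series(movie, phantom_spec.vessel_centers_mm[0])
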