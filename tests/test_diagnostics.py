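"""Zone segmentation, plane statistics and image-quality metrics."""

import math

import numpy as np
import pytest

from grainfield.diagnostics import (MapComparison, area_discrepancy,
                                    compare_maps, contour_polylines,
                                    detect_low_temp_zones, mean_temperature,
                                    psnr, render_contour, ssim)
from grainfield.field_reconstruction import PlanarGrid


def make_grid(values, dx=0.05):
    nz, nx = values.shape
    return PlanarGrid(axes=("x", "z"),
                      axis1_coords=np.arange(nx) * dx + dx / 2,
                      axis2_coords=np.arange(nz) * dx + dx / 2,
                      values=values)


def disk_grid(centers, radius=1.0, cold=10.0, warm=20.0, size=4.0, dx=0.05):
    a = np.arange(dx / 2, size, dx)
    X, Z = np.meshgrid(a, a)
    vals = np.full_like(X, warm)
    for cx, cz in centers:
        vals = np.where(np.hypot(X - cx, Z - cz) < radius, cold, vals)
    return make_grid(vals, dx)


class TestMeanTemperature:
    def test_uniform(self):
        assert mean_temperature(make_grid(np.full((10, 10), 18.0))) == 18.0

    def test_equal_halves(self):
        v = np.full((10, 10), 10.0)
        v[:, 5:] = 20.0
        assert mean_temperature(make_grid(v)) == 15.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(10, 30, (17, 23))
        assert mean_temperature(make_grid(v)) == pytest.approx(
            v.sum() / v.size, abs=1e-12)


class TestZoneDetection:
    def test_warm_grid_has_no_zones(self):
        rep = detect_low_temp_zones(make_grid(np.full((20, 20), 20.0)))
        assert rep.count == 0 and rep.total_area == 0.0

    def test_disk_area_matches_analytic(self):
        rep = detect_low_temp_zones(disk_grid([(2.0, 2.0)]))
        assert rep.count == 1
        assert rep.total_area == pytest.approx(math.pi, rel=0.02)
        assert rep.zones[0].centroid == pytest.approx((2.0, 2.0), abs=0.05)

    def test_three_disks_then_merged_topology(self):
        three = disk_grid([(1.0, 1.0), (3.0, 1.0), (2.0, 3.2)], radius=0.5)
        assert detect_low_temp_zones(three).count == 3
        merged = disk_grid([(1.6, 1.0), (2.4, 1.0), (2.0, 3.2)], radius=0.5)
        assert detect_low_temp_zones(merged).count == 2

    def test_zones_sorted_by_area_descending(self):
        g = disk_grid([(1.0, 1.0)], radius=0.4)
        g.values[np.hypot(*(np.array(np.meshgrid(g.axis1_coords,
                                                 g.axis2_coords))
                            - np.array([3.0, 3.0])[:, None, None])) < 0.8] = 10.0
        rep = detect_low_temp_zones(g)
        areas = [z.area for z in rep.zones]
        assert areas == sorted(areas, reverse=True)
        assert [z.label for z in rep.zones] == [1, 2]

    def test_minimum_zone_filter_suppresses_single_nodes(self):
        v = np.full((40, 40), 20.0)
        v[10, 10] = 10.0  # one cold cell of 0.0025 m^2 at dx=0.05
        rep = detect_low_temp_zones(make_grid(v), min_zone_area=0.05)
        assert rep.count == 0

    def test_total_area_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        base = 18.0 + rng.normal(0, 2.5, (30, 30))
        from scipy.ndimage import gaussian_filter
        g = make_grid(gaussian_filter(base, 2.0))
        areas = [detect_low_temp_zones(g, thr, min_zone_area=0.0).total_area
                 for thr in (14.0, 15.0, 16.0, 17.0, 18.0)]
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_area_converges_with_grid_refinement(self):
        # smooth radial field: sub-15 region is the unit disk
        def cone(dx):
            a = np.arange(dx / 2, 4.0, dx)
            X, Z = np.meshgrid(a, a)
            return make_grid(10.0 + 5.0 * np.hypot(X - 2, Z - 2), dx)

        coarse = detect_low_temp_zones(cone(0.2)).total_area
        fine = detect_low_temp_zones(cone(0.05)).total_area
        assert abs(fine - math.pi) <= abs(coarse - math.pi)
        assert fine == pytest.approx(math.pi, rel=0.01)

    def test_report_serialization(self, tmp_path):
        rep = detect_low_temp_zones(disk_grid([(2.0, 2.0)]), date="2020-08-01",
                                    plane="XOZ")
        df = rep.to_frame()
        assert list(df["zone"]) == [1]
        rep.to_json(tmp_path / "z.json")
        import json
        payload = json.loads((tmp_path / "z.json").read_text())
        assert payload["total_area_m2"] == pytest.approx(rep.total_area)

    def test_non_finite_grid_rejected(self):
        v = np.full((5, 5), 20.0)
        v[2, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            detect_low_temp_zones(make_grid(v))


class TestAreaDiscrepancy:
    @pytest.mark.parametrize("monitored, simulated, abs_err, rel_err", [
        (27.02, 26.51, 0.51, 1.89),   # day-2 validation pair
        (15.1, 14.58, 0.52, 3.44),    # day-7 pair
        (3.75, 3.92, 0.17, 4.53),     # day-14 pair
    ])
    def test_reported_pairs(self, monitored, simulated, abs_err, rel_err):
        a, r = area_discrepancy(monitored, simulated)
        assert a == abs_err
        assert r == rel_err

    def test_equal_areas(self):
        assert area_discrepancy(5.0, 5.0) == (0.0, 0.0)

    def test_monitored_must_be_positive(self):
        with pytest.raises(ValueError):
            area_discrepancy(0.0, 1.0)


def gaussian_window_ssim_oracle(a, b, data_range=255.0, sigma=1.5, radius=5,
                                K1=0.01, K2=0.03):
    """Direct windowed SSIM: explicit 11x11 Gaussian weights, interior
    pixels only (the cropped mean convention)."""
    x = np.arange(-radius, radius + 1)
    w1 = np.exp(-x**2 / (2 * sigma**2))
    w1 /= w1.sum()
    W = np.outer(w1, w1)
    C1, C2 = (K1 * data_range) ** 2, (K2 * data_range) ** 2
    a = a.astype(float)
    b = b.astype(float)
    rows, cols = a.shape
    vals = []
    for i in range(radius, rows - radius):
        for j in range(cols - 2 * radius):
            wa = a[i - radius:i + radius + 1, j:j + 2 * radius + 1]
            wb = b[i - radius:i + radius + 1, j:j + 2 * radius + 1]
            mu_a = (W * wa).sum()
            mu_b = (W * wb).sum()
            var_a = (W * wa**2).sum() - mu_a**2
            var_b = (W * wb**2).sum() - mu_b**2
            cov = (W * wa * wb).sum() - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + C1) * (2 * cov + C2))
                        / ((mu_a**2 + mu_b**2 + C1) * (var_a + var_b + C2)))
    return float(np.mean(vals))


class TestImageMetrics:
    def test_psnr_identity_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        b = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        assert psnr(a, a) == math.inf
        assert psnr(a, b) == pytest.approx(psnr(b, a))

    def test_psnr_uniform_unit_difference_closed_form(self):
        a = np.full((32, 32), 100, dtype=np.uint8)
        b = np.full((32, 32), 101, dtype=np.uint8)
        assert psnr(a, b, peak=255) == pytest.approx(20 * math.log10(255))

    def test_ssim_self_similarity(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 255, (24, 24)).astype(np.uint8)
        assert ssim(a, a) == 1.0
        const = np.full((24, 24), 77, dtype=np.uint8)
        assert ssim(const, const.copy()) == 1.0

    def test_ssim_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        b = np.clip(a.astype(int) + rng.integers(-30, 30, (16, 16)),
                    0, 255).astype(np.uint8)
        assert ssim(a, b) == pytest.approx(
            gaussian_window_ssim_oracle(a, b), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            psnr(np.zeros((4, 4)), np.zeros((4, 5)))
        with pytest.raises(ValueError, match="shape"):
            ssim(np.zeros((4, 4)), np.zeros((5, 4)))

    def test_map_comparison_invariant(self):
        with pytest.raises(ValueError):
            MapComparison(mse=0.0, psnr_db=42.0, ssim=1.0)
        cmp = compare_maps(np.zeros((16, 16)), np.zeros((16, 16)))
        assert cmp.mse == 0.0 and math.isinf(cmp.psnr_db) and cmp.ssim == 1.0


class TestRendering:
    def test_constant_grid_renders_single_color(self):
        img = render_contour(make_grid(np.full((10, 10), 18.0)))
        assert img.dtype == np.uint8
        assert len(np.unique(img)) == 1

    def test_rendering_is_deterministic(self):
        rng = np.random.default_rng(5)
        g = make_grid(rng.uniform(10, 30, (20, 20)))
        assert np.array_equal(render_contour(g), render_contour(g))
        assert render_contour(g).tobytes() == render_contour(g).tobytes()

    def test_non_finite_rendering_rejected(self):
        v = np.full((5, 5), 20.0)
        v[0, 0] = np.inf
        with pytest.raises(ValueError):
            render_contour(make_grid(v))

    def test_smooth_cone_contour_length(self):
        # 15 degC contour of T = 10 + 5 r is the unit circle
        dx = 0.05
        a = np.arange(dx / 2, 4.0, dx)
        X, Z = np.meshgrid(a, a)
        g = make_grid(10.0 + 5.0 * np.hypot(X - 2, Z - 2), dx)
        polylines = contour_polylines(g, 15.0)
        length = sum(np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1])).sum()
                     for c in polylines)
        assert length == pytest.approx(2 * math.pi, rel=0.02)
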