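"""Polygon morphometry, cap/cortex offset geometry, per-embryo
normalization and the area-intensity regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apicodyn.morphometry import (area_intensity_regression,
                                  build_cap_and_cortex, normalize_per_embryo,
                                  polygon_area, region_mean_intensity)


def regular_polygon(n, r, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


class TestPolygonArea:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0, abs=1e-12)

    def test_regular_hexagon_closed_form(self):
        hexagon = regular_polygon(6, 1.0)
        assert polygon_area(hexagon) == pytest.approx(3 * np.sqrt(3) / 2,
                                                      abs=1e-12)

    def test_360gon_approximates_circle(self, circle_360gon):
        # inscribed n-gon area (n/2) r^2 sin(2 pi / n) -> pi r^2
        assert polygon_area(circle_360gon) == pytest.approx(25 * np.pi,
                                                            rel=5e-4)

    @settings(deadline=None, max_examples=30)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50),
           dy=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle, dx, dy):
        poly = regular_polygon(7, 3.0)
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        moved = poly @ R.T + [dx, dy]
        assert polygon_area(moved) == pytest.approx(polygon_area(poly),
                                                    rel=1e-9)

    def test_orientation_reversal_invariance(self, unit_square):
        assert polygon_area(unit_square[::-1]) == pytest.approx(1.0)

    def test_too_few_vertices_names_cell(self):
        with pytest.raises(ValueError, match="cell c7"):
            polygon_area([(0, 0), (1, 1)], cell_id="c7")

    def test_self_intersection_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError, match="not simple"):
            polygon_area(bowtie, cell_id="c1")


class TestCapAndCortex:
    def test_annulus_closed_form(self, circle_360gon):
        _, band = build_cap_and_cortex(circle_360gon, 0.5)
        target = np.pi * (5.5**2 - 5.0**2)
        assert band.area == pytest.approx(target, rel=2e-3)

    def test_square_round_join_closed_form(self):
        # convex round-join offset: band = P*w + pi w^2
        sq = [(0, 0), (4, 0), (4, 4), (0, 4)]
        _, band = build_cap_and_cortex(sq, 0.5, quad_segs=600)
        assert band.area == pytest.approx(8 + np.pi * 0.25, abs=1e-6)

    def test_zero_width_identity(self, unit_square):
        cap, band = build_cap_and_cortex(unit_square, 0.0)
        assert band.is_empty or band.area == 0
        assert cap.area == pytest.approx(1.0)

    @pytest.mark.parametrize("w", [0.1, 0.5, 1.0])
    def test_partition_property(self, w):
        poly = regular_polygon(9, 4.0)
        cap, band = build_cap_and_cortex(poly, w, quad_segs=128)
        grown_area = polygon_area(poly) + w * 9 * 2 * 4.0 * np.sin(np.pi / 9) \
            + np.pi * w**2
        assert cap.area + band.area == pytest.approx(grown_area, rel=1e-4)
        # exact partition: cap + band equals the buffered polygon
        from shapely.geometry import Polygon
        grown = Polygon(poly).buffer(w, quad_segs=128)
        assert cap.area + band.area == pytest.approx(grown.area, rel=1e-9)

    def test_band_tends_to_perimeter_times_width(self):
        poly = regular_polygon(6, 2.0)
        P = 6 * 2 * 2.0 * np.sin(np.pi / 6)
        for w in (1e-2, 1e-3):
            _, band = build_cap_and_cortex(poly, w, quad_segs=64)
            assert band.area / (P * w) == pytest.approx(1.0, rel=5 * w)

    def test_negative_width_rejected(self, unit_square):
        with pytest.raises(ValueError):
            build_cap_and_cortex(unit_square, -0.1)


class TestRegionMeanIntensity:
    def _square_region(self, side):
        cap, _ = build_cap_and_cortex(
            [(0, 0), (side, 0), (side, side), (0, side)], 0)
        return cap

    def test_constant_field(self):
        raster = np.full((50, 50), 7.0)
        reg = self._square_region(4.0)
        assert region_mean_intensity(raster, reg, 0.1).mean == 7.0

    def test_half_split_symmetry(self):
        raster = np.zeros((40, 40))
        raster[:, 20:] = 10.0
        reg = self._square_region(4.0)
        assert region_mean_intensity(raster, reg, 0.1).mean == pytest.approx(5.0)

    def test_linear_ramp_analytic_mean(self):
        px = 0.1
        raster = np.tile((np.arange(120) + 0.5) * px, (120, 1))
        reg = self._square_region(10.0)
        res = region_mean_intensity(raster, reg, px)
        assert res.mean == pytest.approx(5.0, abs=0.05)

    def test_matches_brute_force_pixel_loop(self, rng):
        from shapely.geometry import Point, Polygon
        raster = rng.normal(0, 1, (30, 30))
        poly = Polygon(regular_polygon(8, 1.1, center=(1.5, 1.4)))
        px = 0.1
        res = region_mean_intensity(raster, poly, px)
        vals = [raster[r, c]
                for r in range(30) for c in range(30)
                if poly.contains(Point((c + 0.5) * px, (r + 0.5) * px))]
        assert res.n_pixels == len(vals)
        assert res.mean == pytest.approx(np.mean(vals), abs=0)

    def test_region_too_small_for_resolution(self):
        raster = np.ones((10, 10))
        tiny = self._square_region(0.2)
        with pytest.raises(ValueError, match="pixel"):
            region_mean_intensity(raster, tiny, 1.0)


class TestNormalizePerEmbryo:
    def _records(self, caps, embryos):
        return pd.DataFrame({"embryo_id": embryos, "cap_AU": caps,
                             "cortex_AU": caps, "group": "pHH3+"})

    def test_forced_arithmetic(self):
        out = normalize_per_embryo(self._records([2.0, 4.0, 6.0], ["e0"] * 3))
        assert list(out["cap_pct"]) == pytest.approx([50, 100, 150])

    def test_single_cell_identity(self):
        out = normalize_per_embryo(self._records([3.7], ["e0"]))
        assert out["cap_pct"].iloc[0] == pytest.approx(100.0)

    def test_embryo_mean_is_100(self, rng):
        caps = rng.lognormal(3, 0.5, 60)
        embryos = np.repeat(["e0", "e1", "e2"], 20)
        out = normalize_per_embryo(self._records(caps, embryos))
        for _, g in out.groupby("embryo_id"):
            assert g["cap_pct"].mean() == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance_across_embryos(self, rng):
        shape = rng.lognormal(0, 0.4, 25)
        caps = np.concatenate([10 * shape, 40 * shape])
        embryos = np.repeat(["e0", "e1"], 25)
        out = normalize_per_embryo(self._records(caps, embryos))
        a = out[out.embryo_id == "e0"]["cap_pct"].to_numpy()
        b = out[out.embryo_id == "e1"]["cap_pct"].to_numpy()
        assert a == pytest.approx(b, rel=1e-12)

    def test_idempotent_after_one_application(self, rng):
        caps = rng.lognormal(3, 0.5, 30)
        out1 = normalize_per_embryo(self._records(caps, ["e0"] * 30))
        again = out1.copy()
        again["cap_AU"] = again["cap_pct"]
        again["cortex_AU"] = again["cortex_pct"]
        out2 = normalize_per_embryo(again)
        assert out2["cap_pct"].to_numpy() == pytest.approx(
            out1["cap_pct"].to_numpy(), rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_per_embryo(self._records([0.0, 0.0], ["e0", "e0"]))


class TestAreaIntensityRegression:
    def test_exact_linearity(self):
        df = pd.DataFrame({"group": "pHH3+", "area_um2": [1, 2, 3],
                           "cap_pct": [2, 4, 6]})
        res = area_intensity_regression(df, "pHH3+")
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_too_few_records(self):
        df = pd.DataFrame({"group": "pHH3+", "area_um2": [1, 2],
                           "cap_pct": [2, 4]})
        with pytest.raises(ValueError):
            area_intensity_regression(df, "pHH3+")
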