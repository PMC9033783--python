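"""Contour-level geometry: Dice, Hausdorff, millilitre difference,
mask-to-polygon conversion — each checked against an independent oracle."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from shapely.affinity import scale as shapely_scale, translate
from shapely.geometry import MultiPolygon, Polygon, box

from cinecompare import Contour, PixelGeometry, dice, hausdorff_mm, \
    mask_to_contour, ml_diff
from cinecompare.errors import (ConfigurationError, GeometryError,
                                UndefinedMetricError)
from conftest import UNIT_GEOM, star_polygon


def rasterized_dice(a: Polygon, b: Polygon, resolution: float = 0.01
                    ) -> float:
    """Counting oracle: Dice from point membership on a fine grid."""
    minx = min(a.bounds[0], b.bounds[0]) - resolution
    miny = min(a.bounds[1], b.bounds[1]) - resolution
    maxx = max(a.bounds[2], b.bounds[2]) + resolution
    maxy = max(a.bounds[3], b.bounds[3]) + resolution
    xs = np.arange(minx, maxx, resolution) + resolution / 2
    ys = np.arange(miny, maxy, resolution) + resolution / 2
    gx, gy = np.meshgrid(xs, ys)
    in_a = shapely.contains_xy(a, gx.ravel(), gy.ravel())
    in_b = shapely.contains_xy(b, gx.ravel(), gy.ravel())
    return 100.0 * 2.0 * np.sum(in_a & in_b) / (np.sum(in_a) + np.sum(in_b))


def brute_force_hd(a: Contour, b: Contour, g: PixelGeometry,
                   densify: float) -> float:
    """Independent discrete Hausdorff: own densification, full pairwise
    double maximum via numpy broadcasting."""
    def points(c):
        polys = c.geometry.geoms if c.geometry.geom_type == "MultiPolygon" \
            else [c.geometry]
        pts = []
        for poly in polys:
            for ring in [poly.exterior, *poly.interiors]:
                xy = np.asarray(ring.coords) * [g.spacing_col, g.spacing_row]
                for p0, p1 in zip(xy[:-1], xy[1:]):
                    length = math.dist(p0, p1)
                    n = max(1, math.ceil(length / densify))
                    for i in range(n):
                        pts.append(p0 + (i / n) * (p1 - p0))
        return np.array(pts)

    pa, pb = points(a), points(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestDice:
    def test_identity_is_exactly_100(self):
        c = Contour("lv_endo", box(0, 0, 1, 1))
        assert dice(c, c) == 100.0

    def test_disjoint_is_zero(self):
        a = Contour("lv_endo", box(0, 0, 1, 1))
        b = Contour("lv_endo", box(5, 0, 6, 1))
        assert dice(a, b) == 0.0

    def test_half_overlapping_unit_squares(self):
        a = Contour("lv_endo", box(0, 0, 1, 1))
        b = Contour("lv_endo", box(0.5, 0, 1.5, 1))
        assert dice(a, b) == pytest.approx(50.0, abs=1e-12)
        oracle = rasterized_dice(a.geometry, b.geometry)
        assert dice(a, b) == pytest.approx(oracle, abs=0.5)

    def test_agrees_with_rasterization_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            a = Contour("lv_endo", star_polygon(rng))
            shift = rng.uniform(-1.5, 1.5, size=2)
            b = Contour("lv_endo", star_polygon(rng, center=shift))
            assert dice(a, b) == pytest.approx(
                rasterized_dice(a.geometry, b.geometry), abs=0.5)

    def test_symmetry_range_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = Contour("lv_endo", star_polygon(rng))
            b = Contour("lv_endo", star_polygon(
                rng, center=rng.uniform(-2, 2, size=2)))
            d_ab = dice(a, b)
            assert d_ab == pytest.approx(dice(b, a), abs=1e-9)
            assert 0.0 <= d_ab <= 100.0
            # anisotropic scaling of both contours preserves Dice
            sa = Contour("lv_endo", shapely_scale(
                a.geometry, 2.0, 0.5, origin=(0, 0)))
            sb = Contour("lv_endo", shapely_scale(
                b.geometry, 2.0, 0.5, origin=(0, 0)))
            assert dice(sa, sb) == pytest.approx(d_ab, abs=1e-6)

    def test_respects_holes(self):
        annulus = Polygon(box(0, 0, 4, 4).exterior,
                          [box(1, 1, 3, 3).exterior])
        a = Contour("lv_myo", annulus)
        b = Contour("lv_myo", box(0, 0, 4, 4))
        # |A| = 12, |B| = 16, |A∩B| = 12 → 2·12/28
        assert dice(a, b) == pytest.approx(100.0 * 24 / 28, abs=1e-12)

    def test_both_empty_is_undefined(self):
        e = Contour("lv_endo", Polygon())
        with pytest.raises(UndefinedMetricError):
            dice(e, e)

    def test_one_empty_gives_zero(self):
        a = Contour("lv_endo", box(0, 0, 1, 1))
        assert dice(a, Contour("lv_endo", Polygon())) == 0.0

    def test_self_intersecting_ring_is_repaired_once(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        c = Contour("lv_endo", bowtie)
        assert c.geometry.is_valid
        assert c.area_px == pytest.approx(1.0)  # two half-unit triangles


class TestHausdorff:
    def test_identity_is_zero(self):
        c = Contour("lv_endo", box(0, 0, 1, 1))
        assert hausdorff_mm(c, c, UNIT_GEOM, 0.5) == 0.0

    @pytest.mark.parametrize("spacing_col,expected", [(1.0, 4.0), (2.0, 8.0)])
    def test_separated_squares_scale_with_spacing(self, spacing_col,
                                                  expected):
        g = PixelGeometry(1.0, spacing_col, 8.0)
        a = Contour("lv_endo", box(0, 0, 1, 1))
        b = Contour("lv_endo", box(4, 0, 5, 1))
        value = hausdorff_mm(a, b, g, 0.5)
        assert value == pytest.approx(expected, abs=1e-9)
        assert value == pytest.approx(brute_force_hd(a, b, g, 0.5), abs=1e-9)

    def test_matches_brute_force_oracle_on_random_polygons(self):
        rng = np.random.default_rng(23)
        g = PixelGeometry(1.3, 0.7, 8.0)
        for _ in range(10):
            a = Contour("lv_endo", star_polygon(rng, n=8))
            b = Contour("lv_endo",
                        star_polygon(rng, center=rng.uniform(-2, 2, 2), n=8))
            impl = hausdorff_mm(a, b, g, 0.5)
            assert impl == pytest.approx(brute_force_hd(a, b, g, 0.5),
                                         abs=1e-9)
            assert impl == pytest.approx(hausdorff_mm(b, a, g, 0.5),
                                         abs=1e-12)
            assert impl >= 0.0

    def test_empty_contour_is_undefined(self):
        a = Contour("lv_endo", box(0, 0, 1, 1))
        with pytest.raises(UndefinedMetricError):
            hausdorff_mm(a, Contour("lv_endo", Polygon()), UNIT_GEOM, 0.5)

    def test_densification_bounds_error_against_fine_reference(self):
        # coarse vertex sampling of two concentric squares: true HD is the
        # diagonal corner gap; densified estimate must be within densify_mm
        a = Contour("lv_endo", box(0, 0, 10, 10))
        b = Contour("lv_endo", box(-2, -2, 12, 12))
        truth = 2.0 * math.sqrt(2.0)  # corner-to-corner
        est = hausdorff_mm(a, b, UNIT_GEOM, 0.25)
        assert abs(est - truth) <= 0.25


class TestMlDiff:
    def test_printed_formula_example(self):
        g = PixelGeometry(1.25, 1.25, 8.0)
        a = Contour("lv_endo", box(0, 0, 20, 10))    # 200 px²
        b = Contour("lv_endo", box(0, 0, 10, 10))    # 100 px²
        assert ml_diff(a, b, g, 8.0) == pytest.approx(1.25, abs=1e-12)

    def test_empty_minus_filled(self):
        g = PixelGeometry(1.0, 1.0, 10.0)
        a = Contour("lv_endo", Polygon())
        b = Contour("lv_endo", box(0, 0, 10, 10))
        assert ml_diff(a, b, g, 10.0) == pytest.approx(-1.0, abs=1e-12)

    def test_equal_areas_and_antisymmetry(self):
        rng = np.random.default_rng(3)
        g = PixelGeometry(1.25, 0.9, 8.0)
        for _ in range(10):
            a = Contour("lv_endo", star_polygon(rng))
            b = Contour("lv_endo", star_polygon(rng))
            assert ml_diff(a, b, g, 8.0) == pytest.approx(
                -ml_diff(b, a, g, 8.0), abs=1e-12)
        c = Contour("lv_endo", translate(a.geometry, 5.0, 3.0))
        assert ml_diff(a, c, g, 8.0) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_interval_rejected(self):
        a = Contour("lv_endo", box(0, 0, 1, 1))
        with pytest.raises(ConfigurationError):
            ml_diff(a, a, UNIT_GEOM, 0.0)


class TestMaskToContour:
    def test_single_pixel_is_unit_square(self):
        m = np.zeros((5, 5), dtype=int)
        m[2, 3] = 1
        c = mask_to_contour(m, "lv_endo")
        assert c.area_px == 1.0
        assert c.geometry.bounds == (2.5, 1.5, 3.5, 2.5)  # x=col, y=row

    def test_block_merges_into_one_polygon(self):
        m = np.zeros((4, 4), dtype=int)
        m[1:3, 1:3] = 1
        c = mask_to_contour(m, "lv_endo")
        assert c.geometry.geom_type == "Polygon"
        assert c.area_px == 4.0

    def test_diagonal_pixels_become_multipolygon(self):
        m = np.zeros((3, 3), dtype=int)
        m[0, 0] = m[1, 1] = 1
        c = mask_to_contour(m, "rv_endo")
        assert isinstance(c.geometry, MultiPolygon)
        assert len(c.geometry.geoms) == 2
        assert c.area_px == 2.0

    def test_empty_mask_gives_empty_contour(self):
        assert mask_to_contour(np.zeros((8, 8), dtype=int), "lv_endo").is_empty

    def test_area_equals_popcount_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            shape = rng.integers(1, 33, size=2)
            m = rng.random(shape) < rng.uniform(0.05, 0.6)
            c = mask_to_contour(m, "lv_endo")
            assert c.area_px == float(m.sum())

    def test_non_2d_mask_rejected(self):
        with pytest.raises(GeometryError):
            mask_to_contour(np.zeros((2, 2, 2)), "lv_endo")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(arrays(bool, st.tuples(st.integers(1, 12), st.integers(1, 12))))
def test_mask_area_always_equals_popcount(mask):
    """The polygon outline of any binary mask covers exactly its
    foreground pixels, whatever the connectivity structure."""
    contour = mask_to_contour(mask, "lv_endo")
    assert contour.area_px == float(mask.sum())
    assert contour.is_empty == (mask.sum() == 0)
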