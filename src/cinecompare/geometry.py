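"""Exact contour-level geometry.

Contours are planar polygons (or multipolygons) in continuous pixel
coordinates, with ``x`` running along columns and ``y`` along rows and
pixel centers at integer coordinates. All overlap metrics are computed on
the polygons themselves, not on rasterized approximations: the Dice
coefficient comes from exact intersection areas,

    Dice(A, B) = 2 |A ∩ B| / (|A| + |B|),

the millilitre difference converts the pixel-area difference to volume via
the pixel spacing and the slice interval,

    mlDiff(A, B) = (|A| − |B|) · area-per-pixel · slice-interval / 1000,

and the Hausdorff distance is the symmetric max–min distance between the
two boundaries, evaluated in millimetres on boundaries densified to a user
tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import (GeometryCollection, MultiPolygon, Polygon, box)
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ConfigurationError, GeometryError, UndefinedMetricError

__all__ = [
    "Contour", "PixelGeometry", "dice", "hausdorff_mm", "ml_diff",
    "ml_value", "mask_to_contour",
]


@dataclass(frozen=True)
class PixelGeometry:
    """Physical geometry of one image's pixel grid (all values in mm)."""

    spacing_row: float
    spacing_col: float
    slice_thickness: float
    spacing_between_slices: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("spacing_row", "spacing_col", "slice_thickness"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        if self.spacing_between_slices is not None \
                and not self.spacing_between_slices > 0:
            raise ConfigurationError("spacing_between_slices must be > 0")

    @property
    def area_per_pixel(self) -> float:
        """mm² covered by one pixel."""
        return self.spacing_row * self.spacing_col

    def slice_interval(self, policy: str = "auto") -> float:
        """Inter-slice distance in mm under the given policy."""
        if policy == "thickness":
            return self.slice_thickness
        if policy == "spacing":
            if self.spacing_between_slices is None:
                raise ConfigurationError(
                    "slice_interval_policy='spacing' but "
                    "SpacingBetweenSlices is absent")
            return self.spacing_between_slices
        if policy == "auto":
            if self.spacing_between_slices is not None:
                return self.spacing_between_slices
            return self.slice_thickness
        raise ConfigurationError(f"unknown slice-interval policy {policy!r}")


def _as_polygonal(geom: BaseGeometry, name: str) -> BaseGeometry:
    """Validate/repair a geometry, keeping only its polygonal part.

    Invalid rings get one zero-width-buffer repair pass; anything still
    invalid is an error rather than a silently wrong area.
    """
    if geom.is_empty:
        return Polygon()
    if not isinstance(geom, (Polygon, MultiPolygon, GeometryCollection)):
        raise GeometryError(
            f"contour {name!r}: expected polygonal geometry, got "
            f"{geom.geom_type}")
    if isinstance(geom, GeometryCollection):
        parts = [g for g in geom.geoms if isinstance(g, (Polygon, MultiPolygon))]
        geom = unary_union(parts) if parts else Polygon()
    if not geom.is_valid:
        geom = geom.buffer(0)
        if not geom.is_valid or not isinstance(geom, (Polygon, MultiPolygon)):
            raise GeometryError(
                f"contour {name!r}: geometry invalid and not repairable")
    return geom


@dataclass(frozen=True)
class Contour:
    """A named planar contour in pixel coordinates.

    ``name`` is a contour-type label (``lv_endo``, ``lv_myo``, ``rv_endo``,
    ``lv_papillary``); ``geometry`` is a shapely polygon or multipolygon,
    possibly with interior rings (the myocardium is an annulus whose hole
    is the endocardial border), possibly empty.
    """

    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "geometry", _as_polygonal(self.geometry, self.name))

    @property
    def is_empty(self) -> bool:
        return self.geometry.is_empty

    @property
    def area_px(self) -> float:
        """Area in pixel² (hole areas subtracted)."""
        return self.geometry.area

    def area_mm2(self, g: PixelGeometry) -> float:
        return self.area_px * g.area_per_pixel


def dice(a: Contour, b: Contour) -> float:
    """Dice similarity coefficient of two contours, in percent.

    Computed from exact polygon intersection areas; holes are respected and
    pixel spacing cancels out. Both contours empty is undefined here — the
    comparison layer applies the empty/empty averaging convention before
    calling.
    """
    area_a = a.area_px
    area_b = b.area_px
    if area_a == 0.0 and area_b == 0.0:
        raise UndefinedMetricError(
            "Dice of two empty contours is handled by the averaging "
            "convention, not the geometry layer")
    if a.geometry.equals(b.geometry):
        return 100.0  # exact identity, bypassing overlay rounding noise
    inter = a.geometry.intersection(b.geometry).area
    return min(100.0, max(0.0, 100.0 * 2.0 * inter / (area_a + area_b)))


def _boundary_points_mm(c: Contour, g: PixelGeometry,
                        densify_mm: float) -> np.ndarray:
    """Boundary vertices in mm, densified so no edge exceeds densify_mm."""
    rings: list[np.ndarray] = []
    geoms = c.geometry.geoms if isinstance(c.geometry, MultiPolygon) \
        else [c.geometry]
    for poly in geoms:
        for ring in [poly.exterior, *poly.interiors]:
            xy = np.asarray(ring.coords, dtype=float)
            xy = xy * np.array([g.spacing_col, g.spacing_row])
            rings.append(xy)
    points: list[np.ndarray] = []
    for xy in rings:
        seg_start, seg_end = xy[:-1], xy[1:]
        lengths = np.hypot(*(seg_end - seg_start).T)
        for p0, p1, length in zip(seg_start, seg_end, lengths):
            n = max(1, int(math.ceil(length / densify_mm)))
            t = np.arange(n, dtype=float)[:, None] / n
            points.append(p0 + t * (p1 - p0))
    return np.concatenate(points, axis=0)


def hausdorff_mm(a: Contour, b: Contour, g: PixelGeometry,
                 densify_mm: float = 0.5) -> float:
    """Symmetric Hausdorff distance between two contour boundaries, in mm.

    Vertices are scaled to mm per axis first, every boundary edge is
    subdivided so that no segment is longer than ``densify_mm``, and the
    discrete symmetric Hausdorff distance over the resulting point sets is
    returned. The result is within ``densify_mm`` of the continuous
    boundary-to-boundary Hausdorff distance.
    """
    if densify_mm <= 0:
        raise ConfigurationError("densify_mm must be > 0")
    if a.is_empty or b.is_empty:
        raise UndefinedMetricError(
            "Hausdorff distance undefined for an empty contour")
    pa = _boundary_points_mm(a, g, densify_mm)
    pb = _boundary_points_mm(b, g, densify_mm)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def ml_value(c: Contour, g: PixelGeometry, slice_interval: float) -> float:
    """Volume contribution of one contour on one slice, in ml."""
    if slice_interval <= 0:
        raise ConfigurationError(
            f"slice_interval must be > 0, got {slice_interval}")
    return c.area_px * g.area_per_pixel * slice_interval / 1000.0


def ml_diff(a: Contour, b: Contour, g: PixelGeometry,
            slice_interval: float) -> float:
    """Signed millilitre difference between two contours on one slice.

    Antisymmetric in (a, b); either contour may be empty (area 0). Use
    ``abs(ml_diff(...))`` for per-slice absolute-difference aggregation.
    """
    if slice_interval <= 0:
        raise ConfigurationError(
            f"slice_interval must be > 0, got {slice_interval}")
    return (a.area_px - b.area_px) * g.area_per_pixel \
        * slice_interval / 1000.0


def mask_to_contour(mask: np.ndarray, name: str) -> Contour:
    """Convert a binary pixel mask to its exact polygonal outline.

    Pixel (r, c) becomes the closed unit square
    [c − 0.5, c + 0.5] × [r − 0.5, r + 0.5]; the contour is the union of
    the foreground squares, so its area equals the foreground pixel count
    exactly. 4-connected pixels merge into one polygon; pixels touching
    only diagonally become separate parts of a multipolygon. An all-zero
    mask yields an empty contour.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise GeometryError(f"mask must be 2-D, got shape {mask.shape}")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return Contour(name, Polygon())
    squares = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5)
               for r, c in zip(rows.tolist(), cols.tolist())]
    return Contour(name, unary_union(squares))


def iter_polygons(geom: BaseGeometry) -> Iterable[Polygon]:
    """Yield the polygon parts of a (multi)polygon; nothing if empty."""
    if geom.is_empty:
        return
    if isinstance(geom, MultiPolygon):
        yield from geom.geoms
    else:
        yield geom
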