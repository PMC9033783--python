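"""Shared fixtures: tiny hand-built cases and random-geometry helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from cinecompare import (AnalysisConfig, Case, Contour, ImageRecord,
                         PerturbationModel, PhantomSpec, PixelGeometry,
                         phantom_case_pair)

UNIT_GEOM = PixelGeometry(spacing_row=1.0, spacing_col=1.0,
                          slice_thickness=10.0)


def square_contour(name: str, area: float, origin=(0.0, 0.0)) -> Contour:
    """Axis-aligned square of the given pixel area."""
    side = math.sqrt(area)
    x, y = origin
    return Contour(name, box(x, y, x + side, y + side))


def star_polygon(rng: np.random.Generator, center=(0.0, 0.0),
                 r_min: float = 0.8, r_max: float = 3.0,
                 n: int = 12) -> Polygon:
    """Random simple (possibly concave) star-shaped polygon."""
    angles = np.sort(rng.uniform(0, 2 * math.pi, size=n))
    radii = rng.uniform(r_min, r_max, size=n)
    x = center[0] + radii * np.cos(angles)
    y = center[1] + radii * np.sin(angles)
    return Polygon(np.column_stack([x, y]))


def make_case(cells: dict[tuple[int, int], dict[str, Contour]],
              case_id: str = "case", reader_id: str = "reader",
              geometry: PixelGeometry = UNIT_GEOM,
              config: AnalysisConfig | None = None,
              slice_step: float = 10.0) -> Case:
    """Build a case from a map (slice, phase) → contour dict.

    Slice locations are slice_index * slice_step and trigger times
    phase_index * 50 ms, so the grid reproduces the given indices.
    """
    slices = sorted({s for s, _ in cells})
    phases = sorted({p for _, p in cells})
    records, annotations = [], {}
    for s in slices:
        for p in phases:
            uid = f"uid.{s}.{p}"
            records.append(ImageRecord(
                sop_uid=uid, series_uid="series.1",
                instance_number=s * len(phases) + p + 1,
                slice_location=s * slice_step, geometry=geometry,
                rows=256, cols=256, trigger_time=p * 50.0))
            annotations[uid] = dict(cells.get((s, p), {}))
    return Case.from_images(case_id, reader_id, records, annotations,
                            config or AnalysisConfig())


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(slices=9, phases=5, seed=7)


@pytest.fixture(scope="session")
def identity_pair(small_spec):
    """Phantom compared against an unperturbed copy of itself."""
    return phantom_case_pair(small_spec, PerturbationModel())


@pytest.fixture(scope="session")
def basal_omission_pair(small_spec):
    """Second reader drops the two most basal slices (of nine)."""
    return phantom_case_pair(
        small_spec, PerturbationModel(basal_omission=2, seed=7))
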