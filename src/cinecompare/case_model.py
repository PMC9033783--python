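"""One reader's annotated cine study.

A short-axis cine acquisition is a stack of parallel slices, each imaged
over the cardiac cycle. Images are grouped into a slice × phase grid by
slice location and trigger time; ventricular volumes follow Simpson's
slice-summation rule (sum of contour area × slice interval); the
end-diastolic and end-systolic phases are the volume extrema over the
cycle; the ejection fraction and myocardial mass derive from those.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .config import AnalysisConfig
from .errors import AmbiguityError, MissingStructureError
from .geometry import Contour, PixelGeometry

__all__ = [
    "ImageRecord", "SlicePhaseGrid", "Case", "ClinicalResultSet",
    "build_grid", "detect_phases", "cavity_volume", "clinical_results",
    "CLINICAL_RESULT_NAMES",
]

#: The nine reported clinical results, in reporting order.
CLINICAL_RESULT_NAMES = ("LVEF", "LVEDV", "LVESV", "LVSV", "LVM",
                         "RVEF", "RVEDV", "RVESV", "RVSV")

_CAVITY_CONTOUR = {"lv": "lv_endo", "rv": "rv_endo"}


@dataclass(frozen=True)
class ImageRecord:
    """Geometry and ordering metadata of one DICOM instance."""

    sop_uid: str
    series_uid: str
    instance_number: int
    slice_location: float
    geometry: PixelGeometry
    rows: int
    cols: int
    trigger_time: Optional[float] = None
    series_description: str = ""
    labels: frozenset[str] = frozenset()

    def with_labels(self, extra: Iterable[str]) -> "ImageRecord":
        return ImageRecord(
            self.sop_uid, self.series_uid, self.instance_number,
            self.slice_location, self.geometry, self.rows, self.cols,
            self.trigger_time, self.series_description,
            self.labels | frozenset(extra))


@dataclass
class SlicePhaseGrid:
    """Slice × phase organisation of a cine stack.

    Slice indices follow monotonically increasing slice location; phase
    indices follow trigger time (instance number as fallback) within each
    slice. ``cells`` maps (slice_index, phase_index) → sop_uid; missing
    cells are allowed (sparse acquisitions).
    """

    slice_count: int
    phase_count: int
    cells: dict[tuple[int, int], str]
    slice_locations: list[float]
    #: True if the basal end of the heart is at slice index 0. None until
    #: orientation has been determined (see Case.basal_at_low_index).
    basal_at_low: Optional[bool] = None

    def sop_at(self, slice_index: int, phase_index: int) -> Optional[str]:
        return self.cells.get((slice_index, phase_index))

    def position_of(self, sop_uid: str) -> tuple[int, int]:
        for key, uid in self.cells.items():
            if uid == sop_uid:
                return key
        raise KeyError(sop_uid)


def build_grid(images: Iterable[ImageRecord],
               slice_tolerance_mm: float = 0.5) -> SlicePhaseGrid:
    """Sort images into a slice × phase grid.

    Slice locations within ``slice_tolerance_mm`` of each other collapse
    into one slice (floating-point jitter in DICOM exports). Within a
    slice, phases are ordered by trigger time, falling back to instance
    number when trigger times are absent. The result is independent of
    input ordering.
    """
    records = sorted(images, key=lambda r: (r.slice_location, r.sop_uid))
    if not records:
        raise MissingStructureError("no images to build a grid from")

    slice_groups: list[list[ImageRecord]] = []
    locations: list[float] = []
    for rec in records:
        if slice_groups and rec.slice_location - locations[-1] \
                <= slice_tolerance_mm:
            slice_groups[-1].append(rec)
        else:
            slice_groups.append([rec])
            locations.append(rec.slice_location)

    cells: dict[tuple[int, int], str] = {}
    phase_count = 0
    for s, group in enumerate(slice_groups):
        def phase_key(r: ImageRecord):
            t = r.trigger_time if r.trigger_time is not None else float("inf")
            return (t, r.instance_number)

        group = sorted(group, key=phase_key)
        for prev, curr in zip(group, group[1:]):
            if phase_key(prev) == phase_key(curr):
                raise AmbiguityError(
                    f"images {prev.sop_uid} and {curr.sop_uid} claim the "
                    f"same (slice, phase) cell: slice_location="
                    f"{curr.slice_location}, trigger_time="
                    f"{curr.trigger_time}, instance_number="
                    f"{curr.instance_number}")
        for p, rec in enumerate(group):
            cells[(s, p)] = rec.sop_uid
        phase_count = max(phase_count, len(group))

    return SlicePhaseGrid(len(slice_groups), phase_count, cells, locations)


@dataclass
class Case:
    """One reader's study: images, their grid, and the annotations."""

    case_id: str
    reader_id: str
    images: dict[str, ImageRecord]
    grid: SlicePhaseGrid
    annotations: dict[str, dict[str, Contour]]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        unknown = set(self.annotations) - set(self.images)
        if unknown:
            raise MissingStructureError(
                f"annotated sop_uids not among the case's images: "
                f"{sorted(unknown)[:5]}")

    @classmethod
    def from_images(cls, case_id: str, reader_id: str,
                    images: Iterable[ImageRecord],
                    annotations: Mapping[str, Mapping[str, Contour]],
                    config: Optional[AnalysisConfig] = None) -> "Case":
        config = config or AnalysisConfig()
        image_map = {r.sop_uid: r for r in images}
        grid = build_grid(image_map.values(),
                          config.slice_group_tolerance_mm)
        return cls(case_id, reader_id, image_map, grid,
                   {u: dict(c) for u, c in annotations.items()}, config)

    # -- annotation access -------------------------------------------------

    def contour(self, sop_uid: str, name: str) -> Contour:
        """The named contour on an image; empty if not annotated."""
        from shapely.geometry import Polygon
        entry = self.annotations.get(sop_uid, {})
        return entry.get(name, Contour(name, Polygon()))

    def slice_interval(self, rec: ImageRecord) -> float:
        return rec.geometry.slice_interval(self.config.slice_interval_policy)

    def contoured_slices(self, contours: Optional[Iterable[str]] = None
                         ) -> list[int]:
        """Slice indices carrying any (matching) contour in any phase."""
        wanted = set(contours) if contours is not None else None
        out = set()
        for (s, p), uid in self.grid.cells.items():
            entry = self.annotations.get(uid)
            if not entry:
                continue
            for name, contour in entry.items():
                if contour.is_empty:
                    continue
                if wanted is None or name in wanted:
                    out.add(s)
                    break
        return sorted(out)

    # -- orientation -------------------------------------------------------

    def basal_at_low_index(self) -> bool:
        """Whether slice index 0 is the basal end of the stack.

        Policy ``low``/``high`` is taken verbatim; ``auto`` compares the
        end-diastolic LV cavity area at the two ends of the contoured
        range — the cavity tapers toward the apex, so the larger end is
        basal. Falls back to the RV cavity, then to ``low``.
        """
        policy = self.config.base_direction
        if policy == "low":
            return True
        if policy == "high":
            return False
        for structure in ("lv", "rv"):
            name = _CAVITY_CONTOUR[structure]
            slices = self.contoured_slices([name])
            if not slices:
                continue
            try:
                ed, _ = detect_phases(self, structure)
            except MissingStructureError:
                continue
            lo, hi = slices[0], slices[-1]
            area_lo = self._slice_area(lo, ed, name)
            area_hi = self._slice_area(hi, ed, name)
            return area_lo >= area_hi
        return True

    def _slice_area(self, slice_index: int, phase: int, name: str) -> float:
        uid = self.grid.sop_at(slice_index, phase)
        if uid is None:
            return 0.0
        return self.contour(uid, name).area_px


def _structure_slice_volume(case: Case, uid: str, structure: str) -> float:
    """One image's cavity volume contribution in ml, papillary-adjusted."""
    rec = case.images[uid]
    name = _CAVITY_CONTOUR[structure]
    area = case.contour(uid, name).area_px
    if structure == "lv" \
            and case.config.papillary_policy == "papillary_in_mass":
        area = max(0.0, area - case.contour(uid, "lv_papillary").area_px)
    return area * rec.geometry.area_per_pixel \
        * case.slice_interval(rec) / 1000.0


def cavity_volume(case: Case, structure: str, phase: int) -> float:
    """Slice-summation cavity volume of one phase, in ml.

    Empty or absent contours contribute zero; under the
    ``papillary_in_mass`` policy the papillary area is excluded from the
    LV cavity.
    """
    if structure not in _CAVITY_CONTOUR:
        raise MissingStructureError(f"unknown structure {structure!r}")
    total = 0.0
    for s in range(case.grid.slice_count):
        uid = case.grid.sop_at(s, phase)
        if uid is not None:
            total += _structure_slice_volume(case, uid, structure)
    return total


def _phase_volumes(case: Case, structure: str) -> np.ndarray:
    return np.array([cavity_volume(case, structure, p)
                     for p in range(case.grid.phase_count)])


def detect_phases(case: Case, structure: str) -> tuple[int, int]:
    """End-diastolic and end-systolic phase indices for one ventricle.

    ED is the phase of maximal cavity volume, ES the phase of minimal
    non-zero volume; ties go to the lower phase index. Each ventricle is
    evaluated independently.
    """
    volumes = _phase_volumes(case, structure)
    if not np.any(volumes > 0):
        raise MissingStructureError(
            f"no {structure} cavity contours in case {case.case_id!r}")
    ed = int(np.argmax(volumes))
    nonzero = np.where(volumes > 0)[0]
    es = int(nonzero[np.argmin(volumes[nonzero])])
    return ed, es


@dataclass
class ClinicalResultSet:
    """The nine scalar clinical results of one case.

    Volumes in ml, EF in percent, mass in g. ``None`` marks a result that
    is undefined for the case (e.g. EF with zero EDV, or a ventricle that
    was never contoured).
    """

    values: dict[str, Optional[float]]
    ed_phase: dict[str, Optional[int]]
    es_phase: dict[str, Optional[int]]

    def __getitem__(self, name: str) -> Optional[float]:
        return self.values[name]

    def as_dict(self) -> dict[str, Optional[float]]:
        return dict(self.values)


def _myocardial_mass(case: Case, ed_phase: int) -> float:
    """LV myocardial volume at end-diastole times tissue density, in g."""
    density = case.config.myocardial_density
    mass = 0.0
    for s in range(case.grid.slice_count):
        uid = case.grid.sop_at(s, ed_phase)
        if uid is None:
            continue
        rec = case.images[uid]
        vol = case.contour(uid, "lv_myo").area_px \
            * rec.geometry.area_per_pixel * case.slice_interval(rec) / 1000.0
        if case.config.papillary_policy == "papillary_in_mass":
            vol += case.contour(uid, "lv_papillary").area_px \
                * rec.geometry.area_per_pixel \
                * case.slice_interval(rec) / 1000.0
        mass += vol * density
    return mass


def clinical_results(case: Case) -> ClinicalResultSet:
    """Compute the full clinical-result set of a case.

    EDV/ESV come from the detected extremal phases, SV = EDV − ESV,
    EF = 100 · SV / EDV (undefined when EDV = 0), and the myocardial mass
    is the end-diastolic myocardial volume times the configured density.
    A ventricle without any cavity contour yields missing values rather
    than an error.
    """
    values: dict[str, Optional[float]] = {}
    ed_phases: dict[str, Optional[int]] = {}
    es_phases: dict[str, Optional[int]] = {}
    for structure in ("lv", "rv"):
        prefix = structure.upper()
        try:
            ed, es = detect_phases(case, structure)
        except MissingStructureError:
            for suffix in ("EDV", "ESV", "SV", "EF"):
                values[f"{prefix}{suffix}"] = None
            ed_phases[structure] = es_phases[structure] = None
            if structure == "lv":
                values["LVM"] = None
            continue
        edv = cavity_volume(case, structure, ed)
        esv = cavity_volume(case, structure, es)
        values[f"{prefix}EDV"] = edv
        values[f"{prefix}ESV"] = esv
        values[f"{prefix}SV"] = edv - esv
        values[f"{prefix}EF"] = 100.0 * (edv - esv) / edv if edv > 0 else None
        ed_phases[structure] = ed
        es_phases[structure] = es
        if structure == "lv":
            values["LVM"] = _myocardial_mass(case, ed)
    return ClinicalResultSet(values, ed_phases, es_phases)
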