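"""Synthetic cine-stack fixtures with analytically known volumes.

The phantom emulates a short-axis cine acquisition: a stack of parallel
slices imaged over the cardiac cycle, with an LV cavity (circle), LV
myocardium (annulus of constant wall thickness), RV cavity (half-annulus
crescent hugging the epicardium) and two papillary muscles (small circles
inside the cavity). The radius law is

    r(z, t) = r0 · taper(z) · (1 − α · c(t)),       taper(z) = ((S−z)/S)^e,

with the contraction profile c(t) = (1 − cos 2πτ/1)/2 evaluated on the
cyclic phase fraction τ = min(t, P−t)/P, so that c is exactly symmetric
around mid-cycle and end-diastole sits at phase 0. Contours are regular
polygons, and the ground-truth clinical results use the inscribed-polygon
area (n/2)·r²·sin(2π/n) rather than πr², so a pipeline run on the
unperturbed phantom recovers the truth to floating-point accuracy instead
of a discretisation bound.

A parametric second reader perturbs the truth with per-image rigid
translations, per-vertex radial jitter and omission of basal slices — the
disagreement modes that dominate real interobserver studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage
from shapely.geometry import MultiPolygon, Polygon

from .case_model import Case, ClinicalResultSet, ImageRecord
from .config import AnalysisConfig
from .errors import ConfigurationError, GeometryError
from .geometry import Contour, PixelGeometry
from .io_formats import SAX_CINE_LABEL, AnnotationFile

__all__ = [
    "PhantomSpec", "PerturbationModel", "generate_phantom",
    "perturb_reader", "phantom_case_pair", "write_dicom_stack",
    "circle_polygon_area",
]

_UID_ROOT = "1.2.826.0.1.3680043.8.498"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cine stack.

    Defaults emulate a typical clinical short-axis acquisition: 16 slices
    of 30 phases at 1.25 mm in-plane resolution and 8 mm slice thickness,
    a basal LV radius of 25 mm with a 7 mm wall, and a contraction
    amplitude giving an ejection fraction near 58 %.
    """

    slices: int = 16
    phases: int = 30
    spacing_row: float = 1.25
    spacing_col: float = 1.25
    slice_thickness: float = 8.0
    spacing_between_slices: Optional[float] = None
    rows: int = 160
    cols: int = 160
    lv_radius_mm: float = 25.0          # basal end-diastolic endocardial radius
    wall_thickness_mm: float = 7.0
    rv_width_mm: float = 12.0           # radial extent of the RV crescent
    papillary_radius_mm: float = 3.0    # basal ED radius of each muscle
    taper_exponent: float = 0.5         # base-to-apex radius falloff
    contraction: float = 0.35           # α: peak fractional radius reduction
    vertex_count: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lv_radius_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ConfigurationError("radii and wall thickness must be > 0")
        if not 0 <= self.contraction < 1:
            raise ConfigurationError("contraction must lie in [0, 1)")
        if self.vertex_count < 32:
            raise ConfigurationError("vertex_count must be >= 32")
        if self.slices < 1 or self.phases < 1:
            raise ConfigurationError("slices and phases must be >= 1")

    @property
    def slice_interval(self) -> float:
        return (self.spacing_between_slices
                if self.spacing_between_slices is not None
                else self.slice_thickness)

    def taper(self, z: int) -> float:
        return ((self.slices - z) / self.slices) ** self.taper_exponent

    def contraction_factor(self, t: int) -> float:
        """1 − α·c(t); exactly 1 at t = 0, symmetric around mid-cycle."""
        tau = min(t, self.phases - t) / self.phases
        c = (1.0 - math.cos(2.0 * math.pi * tau)) / 2.0
        return 1.0 - self.contraction * c


@dataclass(frozen=True)
class PerturbationModel:
    """A simulated second reader.

    Translation and radial-noise standard deviations are in mm; basal
    omission removes every contour on that many slices at the basal end
    of the stack (the dominant source of real volume disagreement).
    """

    translation_sd_mm: float = 0.0
    radial_sd_mm: float = 0.0
    basal_omission: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.translation_sd_mm < 0 or self.radial_sd_mm < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.basal_omission < 0:
            raise ConfigurationError("basal_omission must be >= 0")


def circle_polygon_area(radius: float, n: int) -> float:
    """Exact area of the regular n-gon inscribed in a circle."""
    return 0.5 * n * radius * radius * math.sin(2.0 * math.pi / n)


def _arc_band_area(r_in: float, r_out: float, span: float, k: int) -> float:
    """Exact area of a polygonal annular band over an arc of ``span`` rad
    discretised into k segments per arc."""
    return 0.5 * k * (r_out ** 2 - r_in ** 2) * math.sin(span / k)


def _circle_px(cx: float, cy: float, r_mm: float, spec: PhantomSpec,
               n: Optional[int] = None) -> Polygon:
    n = n or spec.vertex_count
    theta = 2.0 * math.pi * np.arange(n) / n
    x = cx + (r_mm / spec.spacing_col) * np.cos(theta)
    y = cy + (r_mm / spec.spacing_row) * np.sin(theta)
    return Polygon(np.column_stack([x, y]))


def _ring_px(cx: float, cy: float, r_mm: float, spec: PhantomSpec
             ) -> np.ndarray:
    n = spec.vertex_count
    theta = 2.0 * math.pi * np.arange(n) / n
    x = cx + (r_mm / spec.spacing_col) * np.cos(theta)
    y = cy + (r_mm / spec.spacing_row) * np.sin(theta)
    return np.column_stack([x, y])


def _crescent_px(cx: float, cy: float, r_in: float, r_out: float,
                 spec: PhantomSpec) -> Polygon:
    """Half-annulus between r_in and r_out on the left of the center."""
    k = spec.vertex_count // 2
    theta = math.pi / 2.0 + math.pi * np.arange(k + 1) / k
    sx, sy = spec.spacing_col, spec.spacing_row
    outer = np.column_stack([cx + (r_out / sx) * np.cos(theta),
                             cy + (r_out / sy) * np.sin(theta)])
    inner = np.column_stack([cx + (r_in / sx) * np.cos(theta[::-1]),
                             cy + (r_in / sy) * np.sin(theta[::-1])])
    return Polygon(np.vstack([outer, inner]))


def _sop_uid(seed: int, z: int, t: int) -> str:
    return f"{_UID_ROOT}.{seed}.{z + 1}.{t + 1}"


def generate_phantom(spec: PhantomSpec,
                     config: Optional[AnalysisConfig] = None
                     ) -> tuple[list[ImageRecord], AnnotationFile,
                                ClinicalResultSet]:
    """Generate image metadata, truth contours and truth clinical results.

    The returned clinical results are computed from the closed-form
    polygon areas of the generated contours, under the given analysis
    configuration (density, papillary policy, slice-interval policy), so
    a pipeline run on the unperturbed annotation reproduces them to
    floating-point accuracy.
    """
    config = config or AnalysisConfig()
    geometry = PixelGeometry(spec.spacing_row, spec.spacing_col,
                             spec.slice_thickness,
                             spec.spacing_between_slices)
    interval = geometry.slice_interval(config.slice_interval_policy)
    cx, cy = spec.cols / 2.0, spec.rows / 2.0
    series_uid = f"{_UID_ROOT}.{spec.seed}.0.0"

    records: list[ImageRecord] = []
    entries: dict[str, dict[str, Contour]] = {}
    n = spec.vertex_count
    k = n // 2
    lv_area = np.zeros((spec.slices, spec.phases))
    rv_area = np.zeros((spec.slices, spec.phases))
    myo_area = np.zeros((spec.slices, spec.phases))
    for z in range(spec.slices):
        taper = spec.taper(z)
        for t in range(spec.phases):
            f = spec.contraction_factor(t)
            r = spec.lv_radius_mm * taper * f
            w = spec.wall_thickness_mm
            rv_w = spec.rv_width_mm * taper * f
            pap_r = spec.papillary_radius_mm * taper * f
            pap_off = 0.4 * r

            uid = _sop_uid(spec.seed, z, t)
            records.append(ImageRecord(
                sop_uid=uid, series_uid=series_uid,
                instance_number=z * spec.phases + t + 1,
                slice_location=z * interval,
                geometry=geometry, rows=spec.rows, cols=spec.cols,
                trigger_time=t * 40.0, series_description="cine_sax",
                labels=frozenset({SAX_CINE_LABEL})))

            endo = _circle_px(cx, cy, r, spec)
            myo = Polygon(_ring_px(cx, cy, r + w, spec),
                          [_ring_px(cx, cy, r, spec)])
            rv = _crescent_px(cx, cy, r + w, r + w + rv_w, spec)
            pap = MultiPolygon([
                _circle_px(cx + pap_off / spec.spacing_col, cy, pap_r, spec),
                _circle_px(cx - pap_off / spec.spacing_col, cy, pap_r, spec),
            ])
            entries[uid] = {
                "lv_endo": Contour("lv_endo", endo),
                "lv_myo": Contour("lv_myo", myo),
                "rv_endo": Contour("rv_endo", rv),
                "lv_papillary": Contour("lv_papillary", pap),
            }

            lv_area[z, t] = circle_polygon_area(r, n)
            myo_area[z, t] = circle_polygon_area(r + w, n) \
                - circle_polygon_area(r, n)
            rv_area[z, t] = _arc_band_area(r + w, r + w + rv_w, math.pi, k)
            if config.papillary_policy == "papillary_in_mass":
                lv_area[z, t] -= 2.0 * circle_polygon_area(pap_r, n)
                myo_area[z, t] += 2.0 * circle_polygon_area(pap_r, n)

    annotation = AnnotationFile(reader_id="truth", entries=entries)
    truth = _truth_results(lv_area, rv_area, myo_area, interval, config)
    return records, annotation, truth


def _truth_results(lv_area: np.ndarray, rv_area: np.ndarray,
                   myo_area: np.ndarray, interval: float,
                   config: AnalysisConfig) -> ClinicalResultSet:
    values: dict[str, Optional[float]] = {}
    ed_phase: dict[str, Optional[int]] = {}
    es_phase: dict[str, Optional[int]] = {}
    for structure, areas in (("lv", lv_area), ("rv", rv_area)):
        volumes = areas.sum(axis=0) * interval / 1000.0
        ed = int(np.argmax(volumes))
        nonzero = np.where(volumes > 0)[0]
        es = int(nonzero[np.argmin(volumes[nonzero])])
        prefix = structure.upper()
        values[f"{prefix}EDV"] = float(volumes[ed])
        values[f"{prefix}ESV"] = float(volumes[es])
        values[f"{prefix}SV"] = float(volumes[ed] - volumes[es])
        values[f"{prefix}EF"] = float(100.0 * (volumes[ed] - volumes[es])
                                      / volumes[ed])
        ed_phase[structure] = ed
        es_phase[structure] = es
        if structure == "lv":
            values["LVM"] = float(myo_area[:, ed].sum() * interval / 1000.0
                                  * config.myocardial_density)
    return ClinicalResultSet(values, ed_phase, es_phase)


# --------------------------------------------------------------------------
# Simulated second reader
# --------------------------------------------------------------------------

def _jitter_ring(ring: np.ndarray, sd_px: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Radial per-vertex jitter away from the ring centroid (open ring)."""
    center = ring.mean(axis=0)
    vec = ring - center
    norm = np.hypot(vec[:, 0], vec[:, 1])
    norm[norm == 0] = 1.0
    unit = vec / norm[:, None]
    eps = rng.normal(0.0, 1.0, size=len(ring))
    return ring + unit * eps[:, None] * np.array(sd_px)


def _perturb_polygon(poly: Polygon, shift_px: np.ndarray,
                     sd_px: tuple[float, float],
                     rng: np.random.Generator) -> Polygon:
    def ring_coords(ring):
        xy = np.asarray(ring.coords, dtype=float)[:-1] + shift_px
        if sd_px != (0.0, 0.0):
            xy = _jitter_ring(xy, sd_px, rng)
        return xy

    shell = ring_coords(poly.exterior)
    holes = [ring_coords(r) for r in poly.interiors]
    return Polygon(shell, holes)


def perturb_reader(annotation: AnnotationFile, model: PerturbationModel,
                   records: list[ImageRecord],
                   reader_id: str = "reader_b") -> AnnotationFile:
    """Simulate a second reader by perturbing a truth annotation.

    Each image receives one rigid translation drawn from N(0, sd) in mm
    (applied in pixel coordinates via the per-axis spacing); each contour
    vertex is jittered radially from its ring centroid with N(0, sd) mm;
    all contours on the ``basal_omission`` most basal slices (lowest
    slice locations — the basal end of a generated phantom) are dropped.
    Invalid jittered rings are re-drawn up to 10 times, then repaired or
    rejected. Fully deterministic under the model's seed.
    """
    rng = np.random.default_rng(model.seed)
    by_uid = {r.sop_uid: r for r in records}
    locations = sorted({r.slice_location for r in records})
    omitted = set(locations[:model.basal_omission])

    entries: dict[str, dict[str, Contour]] = {}
    for uid in sorted(annotation.entries):
        rec = by_uid[uid]
        if rec.slice_location in omitted:
            entries[uid] = {}
            continue
        sx, sy = rec.geometry.spacing_col, rec.geometry.spacing_row
        shift_mm = rng.normal(0.0, model.translation_sd_mm, size=2) \
            if model.translation_sd_mm > 0 else np.zeros(2)
        shift_px = np.array([shift_mm[0] / sx, shift_mm[1] / sy])
        sd_px = (model.radial_sd_mm / sx, model.radial_sd_mm / sy)
        if model.radial_sd_mm == 0:
            sd_px = (0.0, 0.0)
        new_contours: dict[str, Contour] = {}
        for name, contour in annotation.entries[uid].items():
            if contour.is_empty:
                new_contours[name] = contour
                continue
            parts = list(contour.geometry.geoms) \
                if isinstance(contour.geometry, MultiPolygon) \
                else [contour.geometry]
            for attempt in range(10):
                new_parts = [_perturb_polygon(p, shift_px, sd_px, rng)
                             for p in parts]
                geom = MultiPolygon(new_parts) if len(new_parts) > 1 \
                    else new_parts[0]
                try:
                    new_contours[name] = Contour(name, geom)
                    break
                except GeometryError:
                    continue
            else:
                raise GeometryError(
                    f"perturbation of contour {name!r} on image {uid} "
                    f"remained invalid after 10 redraws")
        entries[uid] = new_contours
    return AnnotationFile(reader_id=reader_id, entries=entries)


def phantom_case_pair(spec: PhantomSpec, model: PerturbationModel,
                      config: Optional[AnalysisConfig] = None,
                      case_id: str = "phantom"
                      ) -> tuple[Case, Case, ClinicalResultSet]:
    """Convenience: generate a phantom and its perturbed second reader as
    ready-to-compare cases."""
    config = config or AnalysisConfig()
    records, truth_ann, truth = generate_phantom(spec, config)
    reader_b = perturb_reader(truth_ann, model, records)
    case_a = Case.from_images(case_id, "reader_a", records,
                              truth_ann.entries, config)
    case_b = Case.from_images(case_id, "reader_b", records,
                              reader_b.entries, config)
    return case_a, case_b, truth


# --------------------------------------------------------------------------
# DICOM writing (phantom plumbing: lets the DICOM reader be exercised
# end-to-end without patient data)
# --------------------------------------------------------------------------

def write_dicom_stack(records: list[ImageRecord], outdir: str | Path,
                      rows: Optional[int] = None,
                      cols: Optional[int] = None) -> list[Path]:
    """Write one minimal MR DICOM file per record, with flat pixel data."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(records):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = rec.sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = rec.sop_uid
        ds.SeriesInstanceUID = rec.series_uid
        ds.SeriesDescription = rec.series_description
        ds.Modality = "MR"
        ds.InstanceNumber = rec.instance_number
        ds.SliceLocation = rec.slice_location
        if rec.trigger_time is not None:
            ds.TriggerTime = rec.trigger_time
        ds.PixelSpacing = [rec.geometry.spacing_row, rec.geometry.spacing_col]
        ds.SliceThickness = rec.geometry.slice_thickness
        if rec.geometry.spacing_between_slices is not None:
            ds.SpacingBetweenSlices = rec.geometry.spacing_between_slices
        ds.Rows = rows or rec.rows
        ds.Columns = cols or rec.cols
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.zeros((ds.Rows, ds.Columns),
                                dtype=np.uint16).tobytes()
        path = outdir / f"img_{i:05d}.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        paths.append(path)
    return paths


def spec_from_yaml(path: str | Path) -> tuple[PhantomSpec, PerturbationModel]:
    """Load a phantom spec (and optional ``perturbation`` block) from YAML."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    pert = data.pop("perturbation", {}) or {}
    return PhantomSpec(**data), PerturbationModel(**pert)


def truth_to_dict(truth: ClinicalResultSet) -> dict:
    return {"values": truth.values,
            "ed_phase": truth.ed_phase, "es_phase": truth.es_phase}
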