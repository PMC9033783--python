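"""Reading DICOM metadata and (de)serializing annotations.

Annotations travel as a portable JSON file keyed by SOP Instance UID, with
each contour stored as a WKT geometry string in pixel coordinates
(x = column, y = row, pixel centers at integer coordinates). The format is
versioned, diffable and language-neutral.

DICOM reading extracts only the geometry/ordering metadata needed for
metric computation; pixel data is never required.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pydicom
from shapely import wkt as shapely_wkt
from shapely.errors import ShapelyError

from .case_model import ImageRecord
from .config import AnalysisConfig, CONTOUR_NAMES
from .errors import AnnotationFormatError, DicomTagError, VocabularyError
from .geometry import Contour, PixelGeometry

__all__ = [
    "AnnotationFile", "read_annotations", "write_annotations",
    "read_dicom_series", "label_images", "ANNOTATION_FORMAT_VERSION",
    "COORDINATE_CONVENTION", "SAX_CINE_LABEL",
]

ANNOTATION_FORMAT_VERSION = "1.0"
COORDINATE_CONVENTION = "pixel, x=col, y=row, centers at integers"

#: Label marking records as part of the analyzed short-axis cine stack.
SAX_CINE_LABEL = "SAX_CINE"


# --------------------------------------------------------------------------
# Annotation files
# --------------------------------------------------------------------------

@dataclass
class AnnotationFile:
    """One reader's contours for a study, in portable form."""

    reader_id: str
    entries: dict[str, dict[str, Contour]] = field(default_factory=dict)
    version: str = ANNOTATION_FORMAT_VERSION
    convention: str = COORDINATE_CONVENTION

    def contours_for(self, sop_uid: str) -> dict[str, Contour]:
        return self.entries.get(sop_uid, {})


def write_annotations(annotation: AnnotationFile, path: str | Path) -> None:
    """Serialize an annotation file as JSON + WKT."""
    payload = {
        "format_version": annotation.version,
        "reader_id": annotation.reader_id,
        "coordinate_convention": annotation.convention,
        "entries": {
            sop_uid: {name: c.geometry.wkt for name, c in contours.items()}
            for sop_uid, contours in sorted(annotation.entries.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotations(path: str | Path,
                     config: Optional[AnalysisConfig] = None
                     ) -> AnnotationFile:
    """Parse an annotation JSON file.

    Contour names are mapped through the configured alias table and must
    land in the canonical vocabulary unless the config allows passthrough.
    Reading back a written file reproduces every geometry up to vertex
    order and 1e−9 coordinate tolerance.
    """
    config = config or AnalysisConfig()
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"{path}: not valid JSON: {exc}") from exc
    version = payload.get("format_version")
    if version != ANNOTATION_FORMAT_VERSION:
        raise AnnotationFormatError(
            f"{path}: format version {version!r} not supported "
            f"(expected {ANNOTATION_FORMAT_VERSION!r})")
    entries: dict[str, dict[str, Contour]] = {}
    for sop_uid, contours in payload.get("entries", {}).items():
        parsed: dict[str, Contour] = {}
        for raw_name, wkt_string in contours.items():
            name = config.resolve_contour_name(raw_name)
            if name not in CONTOUR_NAMES and not config.allow_unknown_contours:
                raise VocabularyError(
                    f"{path}: unknown contour name {raw_name!r} on image "
                    f"{sop_uid} (vocabulary: {CONTOUR_NAMES})")
            try:
                geom = shapely_wkt.loads(wkt_string)
            except ShapelyError as exc:
                raise AnnotationFormatError(
                    f"{path}: unparseable WKT for contour {raw_name!r} on "
                    f"image {sop_uid}: {exc}") from exc
            parsed[name] = Contour(name, geom)
        entries[sop_uid] = parsed
    return AnnotationFile(payload.get("reader_id", ""), entries,
                          version, payload.get("coordinate_convention",
                                               COORDINATE_CONVENTION))


# --------------------------------------------------------------------------
# DICOM metadata
# --------------------------------------------------------------------------

def _require(ds: pydicom.Dataset, keyword: str, tag: str, path) -> object:
    value = getattr(ds, keyword, None)
    if value is None:
        raise DicomTagError(
            f"{path}: missing mandatory DICOM tag {keyword} {tag}")
    return value

def _slice_location(ds: pydicom.Dataset, path) -> float:
    """Slice position along the stack normal, in mm.

    Uses Slice Location when present, else projects Image Position
    (Patient) onto the normal of the image plane (cross product of the
    row and column direction cosines).
    """
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    ipp = getattr(ds, "ImagePositionPatient", None)
    iop = getattr(ds, "ImageOrientationPatient", None)
    if ipp is None or iop is None:
        raise DicomTagError(
            f"{path}: neither SliceLocation (0020,1041) nor "
            f"ImagePositionPatient/ImageOrientationPatient "
            f"(0020,0032)/(0020,0037) present")
    row = np.array(iop[:3], dtype=float)
    col = np.array(iop[3:], dtype=float)
    normal = np.cross(row, col)
    return float(np.dot(np.array(ipp, dtype=float), normal))


def read_dicom_series(paths: Iterable[str | Path]) -> list[ImageRecord]:
    """Read geometry/ordering metadata from DICOM files.

    Pixel data is skipped. Missing PixelSpacing or SliceThickness is a
    hard error naming the file and tag: computing millilitre metrics
    without them would be silently wrong. Output order follows sop_uid,
    so the result is independent of input ordering.
    """
    records = []
    for path in paths:
        ds = pydicom.dcmread(str(path), stop_before_pixels=True)
        spacing = _require(ds, "PixelSpacing", "(0028,0030)", path)
        thickness = _require(ds, "SliceThickness", "(0018,0050)", path)
        between = getattr(ds, "SpacingBetweenSlices", None)
        geometry = PixelGeometry(
            spacing_row=float(spacing[0]), spacing_col=float(spacing[1]),
            slice_thickness=float(thickness),
            spacing_between_slices=(float(between)
                                    if between is not None else None))
        trigger = getattr(ds, "TriggerTime", None)
        records.append(ImageRecord(
            sop_uid=str(_require(ds, "SOPInstanceUID", "(0008,0018)", path)),
            series_uid=str(getattr(ds, "SeriesInstanceUID", "")),
            instance_number=int(getattr(ds, "InstanceNumber", 0)),
            slice_location=_slice_location(ds, path),
            geometry=geometry,
            rows=int(_require(ds, "Rows", "(0028,0010)", path)),
            cols=int(_require(ds, "Columns", "(0028,0011)", path)),
            trigger_time=float(trigger) if trigger is not None else None,
            series_description=str(getattr(ds, "SeriesDescription", "")),
        ))
    records.sort(key=lambda r: r.sop_uid)
    return records


def label_images(records: Sequence[ImageRecord],
                 pattern: Optional[str] = None,
                 uids: Optional[Iterable[str]] = None,
                 tag: str = SAX_CINE_LABEL) -> list[ImageRecord]:
    """Tag the records belonging to the analyzed cine stack.

    Selection is by series-description regular expression or by an
    explicit SOP UID list. Matching zero records is an error — it would
    produce a silently empty case downstream.
    """
    if (pattern is None) == (uids is None):
        raise ValueError("provide exactly one of pattern or uids")
    if pattern is not None:
        rx = re.compile(pattern)
        selected = {r.sop_uid for r in records
                    if rx.search(r.series_description)}
    else:
        wanted = set(uids)
        selected = {r.sop_uid for r in records if r.sop_uid in wanted}
    if not selected:
        raise VocabularyError(
            f"selector matched no images (pattern={pattern!r}, "
            f"uids={'<list>' if uids is not None else None})")
    return [r.with_labels([tag]) if r.sop_uid in selected else r
            for r in records]


def labelled(records: Iterable[ImageRecord],
             tag: str = SAX_CINE_LABEL) -> list[ImageRecord]:
    """The subset of records carrying a label."""
    return [r for r in records if tag in r.labels]
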