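"""Pairing two readers' cases and decomposing their disagreement.

A case comparison holds one metric row per (image, contour type): Dice,
Hausdorff distance, signed and absolute millilitre difference, plus the
slice's cardiac position (basal / midventricular / apical, defined by the
first reader). Aggregations mirror the two summary layouts of the
reporting module: clinical-result differences with per-structure metric
averages, and metric values by contour type × cardiac position.

Two Dice averaging modes are provided. ``all`` scores every row,
crediting a matching decision not to segment as 100 % and penalising a
one-sided segmentation as 0 % — it rewards correct segmentation
decisions. ``both`` restricts to rows segmented by both readers and
reflects pure area similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor
from typing import Optional

import pandas as pd

from .case_model import CLINICAL_RESULT_NAMES, Case, clinical_results
from .config import REPORTED_CONTOURS
from .errors import ComparabilityError, MissingStructureError, \
    UndefinedMetricError
from .geometry import dice as _dice, hausdorff_mm, ml_diff

__all__ = [
    "MetricRow", "CaseComparison", "compare_cases", "dice_average",
    "classify_positions", "aggregate_by_contour_position", "rows_to_frame",
    "POSITIONS",
]

POSITIONS = ("basal", "midv", "apical")


@dataclass(frozen=True)
class MetricRow:
    """Metric values for one (image, contour type) pair of readers."""

    sop_uid: str
    slice_index: int
    phase_index: int
    contour: str
    position: str
    segmented_a: bool
    segmented_b: bool
    dice: float                    # % (convention value for one-sided rows)
    hd_mm: Optional[float]         # None whenever either side is empty
    ml_diff: float                 # signed, reader A − reader B
    abs_ml_diff: float


@dataclass
class CaseComparison:
    """Two readers' cases over the same images, with their metric rows."""

    case_a: Case
    case_b: Case
    rows: list[MetricRow]
    #: result name → (value_a, value_b, difference a − b); None components
    #: where a value is undefined for a reader.
    cr_diffs: dict[str, tuple[Optional[float], Optional[float],
                              Optional[float]]]
    #: slice index → basal|midv|apical, defined by reader A.
    positions: dict[int, str]

    @property
    def case_id(self) -> str:
        return self.case_a.case_id


def classify_positions(reference: Case) -> dict[int, str]:
    """Split the first reader's contoured slice range into cardiac thirds.

    The contoured range (slices where the reference reader drew any
    contour in any phase, taken as min..max with a gap tolerance) is
    ordered base → apex and split into basal = first ceil(n/3) slices,
    midventricular = next floor(n/3), apical = the remainder. The extra
    slice of a non-divisible count goes to the basal third, where most
    interobserver variability concentrates.
    """
    contoured = reference.contoured_slices()
    if not contoured:
        raise MissingStructureError(
            f"case {reference.case_id!r} has no contoured slices")
    lo, hi = contoured[0], contoured[-1]
    span = list(range(lo, hi + 1))
    if reference.basal_at_low_index():
        ordered = span
    else:
        ordered = span[::-1]
    n = len(ordered)
    n_basal = ceil(n / 3)
    n_midv = floor(n / 3)
    out: dict[int, str] = {}
    for i, s in enumerate(ordered):
        if i < n_basal:
            out[s] = "basal"
        elif i < n_basal + n_midv:
            out[s] = "midv"
        else:
            out[s] = "apical"
    return out


def _position_for(slice_index: int, positions: dict[int, str]) -> str:
    """Position of a slice, clamping indices outside the classified range."""
    if slice_index in positions:
        return positions[slice_index]
    keys = sorted(positions)
    if slice_index < keys[0]:
        return positions[keys[0]]
    return positions[keys[-1]]


def compare_cases(a: Case, b: Case,
                  contours: tuple[str, ...] = REPORTED_CONTOURS
                  ) -> CaseComparison:
    """Build the full comparison of two readers over identical images.

    Emits one metric row per (image, contour type) for every image on a
    slice of reader A's contoured range within an analyzed phase (a phase
    in which either reader segmented anything), plus any image that either
    reader segmented. Empty/empty rows score Dice 100 with zero ml
    difference and no Hausdorff sample; one-sided rows score Dice 0 and
    carry the full slice volume as difference.
    """
    if set(a.images) != set(b.images):
        missing = sorted(set(a.images) ^ set(b.images))
        raise ComparabilityError(
            f"cases reference different images; symmetric difference "
            f"(first 10): {missing[:10]}")

    positions = classify_positions(a)
    densify = a.config.densify_mm

    analyzed_phases = set()
    for case in (a, b):
        for uid, entry in case.annotations.items():
            if any(not c.is_empty for c in entry.values()):
                analyzed_phases.add(case.grid.position_of(uid)[1])

    analyzed_slices = set(positions)
    rows: list[MetricRow] = []
    for (s, p), uid in sorted(a.grid.cells.items()):
        rec = a.images[uid]
        interval = a.slice_interval(rec)
        for name in contours:
            ca = a.contour(uid, name)
            cb = b.contour(uid, name)
            seg_a, seg_b = not ca.is_empty, not cb.is_empty
            in_scope = seg_a or seg_b or (
                s in analyzed_slices and p in analyzed_phases)
            if not in_scope:
                continue
            if seg_a and seg_b:
                d = _dice(ca, cb)
                hd: Optional[float] = hausdorff_mm(ca, cb, rec.geometry,
                                                   densify)
            elif seg_a or seg_b:
                d, hd = 0.0, None
            else:
                d, hd = 100.0, None
            ml = ml_diff(ca, cb, rec.geometry, interval)
            rows.append(MetricRow(
                uid, s, p, name, _position_for(s, positions),
                seg_a, seg_b, d, hd, ml, abs(ml)))

    cr_a = clinical_results(a)
    cr_b = clinical_results(b)
    cr_diffs = {}
    for result in CLINICAL_RESULT_NAMES:
        va, vb = cr_a[result], cr_b[result]
        diff = va - vb if va is not None and vb is not None else None
        cr_diffs[result] = (va, vb, diff)

    return CaseComparison(a, b, rows, cr_diffs, positions)


def dice_average(rows: list[MetricRow], mode: str = "all") -> float:
    """Average Dice over metric rows under one of the two conventions.

    ``all`` averages every row (empty/empty = 100, one-sided = 0);
    ``both`` averages only rows segmented by both readers.
    """
    if mode == "all":
        if not rows:
            raise UndefinedMetricError("no rows to average")
        return sum(r.dice for r in rows) / len(rows)
    if mode == "both":
        both = [r for r in rows if r.segmented_a and r.segmented_b]
        if not both:
            raise UndefinedMetricError(
                "no rows segmented by both readers")
        return sum(r.dice for r in both) / len(both)
    raise ValueError(f"unknown averaging mode {mode!r}")


def rows_to_frame(comparisons: list[CaseComparison]) -> pd.DataFrame:
    """Long-format metric table: one row per (case, image, contour)."""
    records = []
    for comp in comparisons:
        for r in comp.rows:
            records.append({
                "case_id": comp.case_id, "sop_uid": r.sop_uid,
                "slice": r.slice_index, "phase": r.phase_index,
                "contour": r.contour, "position": r.position,
                "segmented_a": r.segmented_a, "segmented_b": r.segmented_b,
                "dice": r.dice, "hd_mm": r.hd_mm, "ml_diff": r.ml_diff,
                "abs_ml_diff": r.abs_ml_diff,
            })
    return pd.DataFrame.from_records(
        records, columns=["case_id", "sop_uid", "slice", "phase", "contour",
                          "position", "segmented_a", "segmented_b", "dice",
                          "hd_mm", "ml_diff", "abs_ml_diff"])


_METRIC_LABELS = ("Dice (all slices) [%]",
                  "Dice (slices contoured by both) [%]",
                  "HD [mm]",
                  "Abs. ml diff. (per slice) [ml]")


def aggregate_by_contour_position(comparisons: list[CaseComparison],
                                  contours: tuple[str, ...] =
                                  REPORTED_CONTOURS) -> pd.DataFrame:
    """Metric summary by cardiac position × contour type.

    Rows are (position, metric) pairs — both Dice averages, mean Hausdorff
    distance over defined rows, and mean per-slice absolute millilitre
    difference — columns are contour types. Cells without any qualifying
    row are NaN.
    """
    if not comparisons:
        raise ComparabilityError("no comparisons to aggregate")
    index = pd.MultiIndex.from_product(
        [POSITIONS, _METRIC_LABELS], names=["position", "metric"])
    table = pd.DataFrame(index=index, columns=list(contours), dtype=float)
    all_rows = [r for comp in comparisons for r in comp.rows]
    for position in POSITIONS:
        for contour in contours:
            rows = [r for r in all_rows
                    if r.position == position and r.contour == contour]
            cell = {label: float("nan") for label in _METRIC_LABELS}
            if rows:
                cell["Dice (all slices) [%]"] = dice_average(rows, "all")
                try:
                    cell["Dice (slices contoured by both) [%]"] = \
                        dice_average(rows, "both")
                except UndefinedMetricError:
                    pass
                hds = [r.hd_mm for r in rows if r.hd_mm is not None]
                if hds:
                    cell["HD [mm]"] = sum(hds) / len(hds)
                cell["Abs. ml diff. (per slice) [ml]"] = \
                    sum(r.abs_ml_diff for r in rows) / len(rows)
            for label, value in cell.items():
                table.loc[(position, label), contour] = value
    return table
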