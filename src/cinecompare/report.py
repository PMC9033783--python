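"""Interobserver statistics and automated report generation.

Bland–Altman analysis plots, for each clinical result, the per-case mean
of the two readers' values against their difference, with agreement limits
at mean ± 1.96 standard deviations of the differences. Differences are
oriented reader A − reader B throughout. Alongside, the module renders the
two standard summary layouts — clinical-result differences with the
segmentation metrics they rest on, and metrics by contour type × cardiac
position — plus the long-format spreadsheets and static figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy import stats

from .case_model import CLINICAL_RESULT_NAMES
from .comparison import (CaseComparison, aggregate_by_contour_position,
                         dice_average, rows_to_frame)
from .config import REPORTED_CONTOURS
from .errors import ComparabilityError, UndefinedMetricError

__all__ = [
    "BlandAltmanResult", "bland_altman", "pearson", "summary_table_cr",
    "cr_table", "render_outputs", "read_report_csv",
]

_LOA_FACTOR = 1.96

#: Clinical results grouped by the structure whose contours they rest on.
_CR_BLOCKS = (
    (("LVEF", "LVEDV", "LVESV"), "lv_endo"),
    (("LVM",), "lv_myo"),
    (("RVEF", "RVEDV", "RVESV"), "rv_endo"),
)


@dataclass
class BlandAltmanResult:
    """Agreement statistics for one clinical result."""

    name: str
    n: int
    mean_diff: float
    sd_diff: Optional[float]            # None when n < 2
    loa_low: Optional[float]            # mean − 1.96 sd
    loa_high: Optional[float]           # mean + 1.96 sd
    points: list[tuple[float, float]]   # ((a+b)/2, a−b) per case


def bland_altman(pairs: Sequence[tuple[float, float]],
                 name: str = "") -> BlandAltmanResult:
    """Bland–Altman statistics for paired reader values.

    Differences are a − b; the standard deviation uses the n − 1
    denominator. With a single pair the mean difference is still reported
    but the limits of agreement are missing.
    """
    if not pairs:
        raise UndefinedMetricError("no pairs for Bland–Altman analysis")
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    means = np.array([(a + b) / 2.0 for a, b in pairs], dtype=float)
    mean_diff = float(diffs.mean())
    if len(pairs) >= 2:
        sd = float(diffs.std(ddof=1))
        loa_low = mean_diff - _LOA_FACTOR * sd
        loa_high = mean_diff + _LOA_FACTOR * sd
    else:
        sd = loa_low = loa_high = None
    return BlandAltmanResult(name, len(pairs), mean_diff, sd,
                             loa_low, loa_high,
                             list(zip(means.tolist(), diffs.tolist())))


def pearson(pairs: Sequence[tuple[float, float]]) -> Optional[float]:
    """Pearson product-moment correlation of paired reader values.

    Returns None (an explicitly missing value) when fewer than two pairs
    exist or either side has zero variance.
    """
    if len(pairs) < 2:
        return None
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    return float(stats.pearsonr(a, b).statistic)


def _cr_pairs(comparisons: Sequence[CaseComparison],
              result: str) -> list[tuple[float, float]]:
    pairs = []
    for comp in comparisons:
        va, vb, _ = comp.cr_diffs[result]
        if va is not None and vb is not None:
            pairs.append((va, vb))
    return pairs


def cr_table(comparisons: Sequence[CaseComparison]) -> pd.DataFrame:
    """Per-case clinical results of both readers and their differences."""
    records = []
    for comp in comparisons:
        for result in CLINICAL_RESULT_NAMES:
            va, vb, diff = comp.cr_diffs[result]
            records.append({"case_id": comp.case_id, "result": result,
                            "value_a": va, "value_b": vb, "diff": diff})
    return pd.DataFrame.from_records(records)


def _metric_block(rows, label_suffix: str = "") -> list[tuple[str, float]]:
    """The three metric summary lines below a clinical-result block."""
    out = []
    try:
        out.append((f"Dice (all slices{label_suffix}) [%]",
                    dice_average(list(rows), "all")))
    except UndefinedMetricError:
        out.append((f"Dice (all slices{label_suffix}) [%]", math.nan))
    try:
        out.append((f"Dice (slices contoured by both{label_suffix}) [%]",
                    dice_average(list(rows), "both")))
    except UndefinedMetricError:
        out.append((f"Dice (slices contoured by both{label_suffix}) [%]",
                    math.nan))
    hds = [r.hd_mm for r in rows if r.hd_mm is not None]
    out.append((f"HD{label_suffix} [mm]",
                sum(hds) / len(hds) if hds else math.nan))
    return out


def summary_table_cr(comparisons: Sequence[CaseComparison]) -> pd.DataFrame:
    """Clinical-result differences joined with the metrics beneath them.

    For every clinical result: mean and standard deviation of the
    reader-A − reader-B differences over cases. Under each block of
    results sit the Dice (both averaging modes) and Hausdorff means of the
    contour type those results rest on; a final block covers all contour
    types together. ``n`` counts the samples behind each line (cases for
    results, metric rows / defined Hausdorff rows for metrics).
    """
    if not comparisons:
        raise ComparabilityError("no comparisons to summarize")
    all_rows = [r for comp in comparisons for r in comp.rows]
    lines = []
    for results, contour in _CR_BLOCKS:
        for result in results:
            diffs = [comp.cr_diffs[result][2] for comp in comparisons
                     if comp.cr_diffs[result][2] is not None]
            mean = float(np.mean(diffs)) if diffs else math.nan
            sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else math.nan
            lines.append({"row": f"{result} [{_cr_unit(result)}]",
                          "mean": mean, "std": sd, "n": len(diffs)})
        contour_rows = [r for r in all_rows if r.contour == contour]
        for label, value in _metric_block(contour_rows):
            n = len(contour_rows) if "Dice" in label else \
                sum(1 for r in contour_rows if r.hd_mm is not None)
            lines.append({"row": label, "mean": value, "std": math.nan,
                          "n": n})
    for label, value in _metric_block(all_rows, label_suffix=", all contours"):
        n = len(all_rows) if "Dice" in label else \
            sum(1 for r in all_rows if r.hd_mm is not None)
        lines.append({"row": label, "mean": value, "std": math.nan, "n": n})
    return pd.DataFrame.from_records(lines, columns=["row", "mean", "std",
                                                     "n"])


def _cr_unit(result: str) -> str:
    if result.endswith("EF"):
        return "%"
    if result == "LVM":
        return "g"
    return "ml"


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def read_report_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Re-parse a rendered CSV to the exact in-memory table.

    Skips the provenance comment header and uses round-trip float parsing
    so every numeric value is restored bit-exactly ('.' decimal, UTF-8).
    """
    return pd.read_csv(path, comment="#", float_precision="round_trip",
                       **kwargs)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    """CSV with a comment header recording provenance conventions."""
    header = (f"# cinecompare; config_hash={config_hash}; "
              f"differences oriented reader A - reader B\n")
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def _bland_altman_figure(ba_results: list[BlandAltmanResult],
                         dice_frame: pd.DataFrame, path: Path) -> None:
    """Overview figure: one Bland–Altman panel per clinical result plus
    the dual Dice boxplots per contour type."""
    n_panels = len(ba_results) + 1
    ncols = 5
    nrows = math.ceil(n_panels / ncols)
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(4 * ncols, 3.2 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for ax, ba in zip(axes, ba_results):
        if ba.points:
            means, diffs = zip(*ba.points)
            sizes = 20 + 180 * np.abs(diffs) / (np.abs(diffs).max() or 1.0)
            ax.scatter(means, diffs, s=sizes, alpha=0.6,
                       edgecolor="k", linewidth=0.5)
        ax.axhline(ba.mean_diff, color="k")
        if ba.loa_low is not None:
            ax.axhline(ba.loa_low, color="k", linestyle="--")
            ax.axhline(ba.loa_high, color="k", linestyle="--")
        ax.set_title(ba.name)
        ax.set_xlabel("mean of readers")
        ax.set_ylabel("difference (A − B)")
    ax = axes[len(ba_results)]
    if not dice_frame.empty:
        sns.boxplot(data=dice_frame, x="contour", y="dice", hue="average",
                    ax=ax)
        ax.set_title("Dice by contour type")
        ax.set_ylabel("Dice [%]")
    for extra in axes[n_panels:]:
        extra.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _per_result_figures(crs: pd.DataFrame, figdir: Path) -> None:
    """Paired boxplot and quantile–quantile plot per clinical result."""
    for result, sub in crs.groupby("result"):
        sub = sub.dropna(subset=["value_a", "value_b"])
        if sub.empty:
            continue
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
        long = sub.melt(value_vars=["value_a", "value_b"],
                        var_name="reader", value_name="value")
        sns.boxplot(data=long, x="reader", y="value", ax=ax1)
        ax1.set_title(f"{result}: reader distributions")
        qa = np.sort(sub["value_a"].to_numpy())
        qb = np.sort(sub["value_b"].to_numpy())
        ax2.plot(qa, qb, "o", alpha=0.7)
        lims = [min(qa.min(), qb.min()), max(qa.max(), qb.max())]
        ax2.plot(lims, lims, "k--", linewidth=0.8)
        ax2.set_xlabel("reader A quantiles")
        ax2.set_ylabel("reader B quantiles")
        ax2.set_title(f"{result}: Q–Q")
        fig.tight_layout()
        fig.savefig(figdir / f"cr_{result.lower()}.png", dpi=110)
        plt.close(fig)


def render_outputs(comparisons: Sequence[CaseComparison],
                   outdir: str | Path) -> dict[str, Path]:
    """Compute every table first, then write spreadsheets and figures.

    Writes crs.csv (per case × clinical result), metrics.csv (long
    format), table1.csv (clinical-result summary), table2.csv (metrics by
    contour × position), pearson.csv, and static figures. Returns a map
    of artefact name → path.
    """
    if not comparisons:
        raise ComparabilityError("no comparisons to render")
    comparisons = list(comparisons)
    config_hash = comparisons[0].case_a.config.hash()

    # all tables computed up front so a rendering failure loses nothing
    crs = cr_table(comparisons)
    metrics = rows_to_frame(comparisons)
    table1 = summary_table_cr(comparisons)
    table2 = aggregate_by_contour_position(comparisons)
    ba_results = []
    pearson_lines = []
    for result in CLINICAL_RESULT_NAMES:
        pairs = _cr_pairs(comparisons, result)
        if pairs:
            ba_results.append(bland_altman(pairs, result))
        pearson_lines.append({"result": result, "pearson_r": pearson(pairs),
                              "n": len(pairs)})
    pearson_df = pd.DataFrame.from_records(pearson_lines)

    dice_long = []
    for contour in REPORTED_CONTOURS:
        rows = [r for c in comparisons for r in c.rows
                if r.contour == contour]
        dice_long += [{"contour": contour, "average": "all", "dice": r.dice}
                      for r in rows]
        dice_long += [{"contour": contour, "average": "both", "dice": r.dice}
                      for r in rows if r.segmented_a and r.segmented_b]
    dice_frame = pd.DataFrame.from_records(dice_long)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    artefacts = {}
    for name, df, index in [("crs", crs, False), ("metrics", metrics, False),
                            ("table1", table1, False),
                            ("table2", table2, True),
                            ("pearson", pearson_df, False)]:
        path = outdir / f"{name}.csv"
        _write_csv(df, path, config_hash, index=index)
        artefacts[name] = path

    overview = figdir / "clinical_results_overview.png"
    _bland_altman_figure(ba_results, dice_frame, overview)
    artefacts["overview_figure"] = overview
    _per_result_figures(crs, figdir)
    return artefacts
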