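"""Case pairing, the two Dice averaging conventions, cardiac-position
classification and the position × contour aggregation."""

import math

import pytest

from cinecompare import (MetricRow, PerturbationModel, PhantomSpec,
                         classify_positions, compare_cases, dice_average,
                         aggregate_by_contour_position, phantom_case_pair)
from cinecompare.comparison import rows_to_frame
from cinecompare.errors import (ComparabilityError, MissingStructureError,
                                UndefinedMetricError)
from conftest import make_case, square_contour


def row(dice=100.0, seg_a=True, seg_b=True, hd=0.0, ml=0.0,
        position="midv", contour="lv_endo") -> MetricRow:
    if not (seg_a and seg_b):
        hd = None
    return MetricRow("uid", 0, 0, contour, position, seg_a, seg_b,
                     dice, hd, ml, abs(ml))


class TestDiceAverage:
    def test_decision_convention(self):
        rows = [row(dice=100.0), row(dice=0.0, seg_b=False)]
        assert dice_average(rows, "all") == 50.0
        assert dice_average(rows, "both") == 100.0

    def test_all_empty_empty_is_perfect(self):
        rows = [row(dice=100.0, seg_a=False, seg_b=False)] * 3
        assert dice_average(rows, "all") == 100.0

    def test_modes_coincide_when_everything_both_segmented(self):
        rows = [row(dice=d) for d in (90.0, 80.0, 70.0)]
        assert dice_average(rows, "all") == dice_average(rows, "both")

    def test_one_sided_rows_do_not_move_the_both_average(self):
        rows = [row(dice=90.0), row(dice=80.0)]
        padded = rows + [row(dice=0.0, seg_a=False)]
        assert dice_average(padded, "both") == dice_average(rows, "both")
        assert dice_average(padded, "all") < dice_average(rows, "all")

    def test_no_both_segmented_rows_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            dice_average([row(seg_a=False, dice=0.0)], "both")


class TestClassifyPositions:
    def _case_with_slices(self, n):
        cells = {(s, 0): {"lv_endo": square_contour(
            "lv_endo", 100 * (n - s))} for s in range(n)}
        return make_case(cells)

    @pytest.mark.parametrize("n,counts", [(9, (3, 3, 3)), (10, (4, 3, 3)),
                                          (2, (1, 0, 1)), (1, (1, 0, 0))])
    def test_third_split_rule(self, n, counts):
        positions = classify_positions(self._case_with_slices(n))
        tally = [sum(1 for v in positions.values() if v == k)
                 for k in ("basal", "midv", "apical")]
        assert tuple(tally) == counts

    def test_base_direction_follows_larger_cavity(self):
        # areas increase with slice index → base at the high end
        cells = {(s, 0): {"lv_endo": square_contour("lv_endo", 100 * (s + 1))}
                 for s in range(9)}
        positions = classify_positions(make_case(cells))
        assert positions[8] == "basal" and positions[0] == "apical"

    def test_depends_only_on_first_reader(self, basal_omission_pair):
        case_a, case_b, _ = basal_omission_pair
        assert classify_positions(case_a) == \
            compare_cases(case_a, case_b).positions

    def test_uncontoured_case_raises(self):
        case = make_case({(0, 0): {}})
        with pytest.raises(MissingStructureError):
            classify_positions(case)


class TestCompareCases:
    def test_identity_profile(self, identity_pair):
        case_a, case_b, _ = identity_pair
        comp = compare_cases(case_a, case_b)
        assert comp.rows
        assert all(r.dice == 100.0 for r in comp.rows)
        assert all(r.hd_mm == 0.0 for r in comp.rows)
        assert all(r.ml_diff == pytest.approx(0.0, abs=1e-12)
                   for r in comp.rows)
        assert all(d[2] == pytest.approx(0.0, abs=1e-9)
                   for d in comp.cr_diffs.values())
        assert dice_average(comp.rows, "all") == 100.0
        assert dice_average(comp.rows, "both") == 100.0

    def test_translation_preserves_volumes_but_not_dice(self):
        spec = PhantomSpec(slices=5, phases=3, seed=2)
        a, b, _ = phantom_case_pair(
            spec, PerturbationModel(translation_sd_mm=1.5, seed=2))
        comp = compare_cases(a, b)
        assert all(r.dice < 100.0 for r in comp.rows)
        assert all(abs(r.ml_diff) < 1e-9 for r in comp.rows)
        for result in ("LVEDV", "LVESV", "RVEDV", "RVESV"):
            assert comp.cr_diffs[result][2] == pytest.approx(0.0, abs=1e-9)

    def test_swapping_readers_negates_differences(self):
        spec = PhantomSpec(slices=4, phases=3, seed=5)
        a, b, _ = phantom_case_pair(
            spec, PerturbationModel(translation_sd_mm=1.0, seed=5))
        fwd = compare_cases(a, b)
        rev = compare_cases(b, a)
        key = lambda r: (r.sop_uid, r.contour)
        rev_map = {key(r): r for r in rev.rows}
        for r in fwd.rows:
            s = rev_map[key(r)]
            assert s.ml_diff == pytest.approx(-r.ml_diff, abs=1e-12)
            assert s.dice == pytest.approx(r.dice, abs=1e-9)
            if r.hd_mm is not None:
                assert s.hd_mm == pytest.approx(r.hd_mm, abs=1e-9)
        for name, (va, vb, d) in fwd.cr_diffs.items():
            assert rev.cr_diffs[name][2] == pytest.approx(-d, abs=1e-9)

    def test_missing_basal_slice_scores_one_sided(self, basal_omission_pair):
        case_a, case_b, _ = basal_omission_pair
        comp = compare_cases(case_a, case_b)
        one_sided = [r for r in comp.rows if r.segmented_a != r.segmented_b]
        assert one_sided
        assert {r.slice_index for r in one_sided} == {0, 1}
        assert all(r.position == "basal" for r in one_sided)
        assert all(r.dice == 0.0 and r.hd_mm is None for r in one_sided)
        for r in one_sided:
            rec = case_a.images[r.sop_uid]
            full = case_a.contour(r.sop_uid, r.contour).area_px \
                * rec.geometry.area_per_pixel \
                * case_a.slice_interval(rec) / 1000.0
            assert r.ml_diff == pytest.approx(full, abs=1e-12)

    def test_mismatched_image_sets_rejected(self, identity_pair):
        case_a, _, _ = identity_pair
        other, _, _ = phantom_case_pair(PhantomSpec(slices=2, phases=2,
                                                    seed=99),
                                        PerturbationModel())
        with pytest.raises(ComparabilityError):
            compare_cases(case_a, other)


class TestAggregation:
    def test_identity_yields_perfect_cells(self, identity_pair):
        case_a, case_b, _ = identity_pair
        table = aggregate_by_contour_position([compare_cases(case_a, case_b)])
        for position in ("basal", "midv", "apical"):
            for contour in ("lv_endo", "lv_myo", "rv_endo"):
                cell = table.loc[position, contour]
                assert cell["Dice (all slices) [%]"] == 100.0
                assert cell["HD [mm]"] == 0.0
                assert cell["Abs. ml diff. (per slice) [ml]"] == \
                    pytest.approx(0.0, abs=1e-12)

    def test_basal_omission_lowers_basal_dice_only(self, basal_omission_pair):
        case_a, case_b, _ = basal_omission_pair
        table = aggregate_by_contour_position([compare_cases(case_a, case_b)])
        for contour in ("lv_endo", "lv_myo", "rv_endo"):
            basal = table.loc[("basal", "Dice (all slices) [%]"), contour]
            midv = table.loc[("midv", "Dice (all slices) [%]"), contour]
            assert basal < midv

    def test_single_row_cell_equals_row_value(self):
        cells_a = {(0, 0): {"lv_endo": square_contour("lv_endo", 100)}}
        cells_b = {(0, 0): {"lv_endo": square_contour(
            "lv_endo", 100, origin=(5.0, 0.0))}}
        comp = compare_cases(make_case(cells_a), make_case(cells_b))
        table = aggregate_by_contour_position([comp])
        [r] = [r for r in comp.rows if r.contour == "lv_endo"]
        assert table.loc[("basal", "Dice (all slices) [%]"), "lv_endo"] \
            == r.dice
        assert table.loc[("basal", "HD [mm]"), "lv_endo"] == r.hd_mm
        assert math.isnan(table.loc[("midv", "HD [mm]"), "lv_endo"])

    def test_empty_comparison_list_rejected(self):
        with pytest.raises(ComparabilityError):
            aggregate_by_contour_position([])

    def test_long_format_frame_columns(self, identity_pair):
        case_a, case_b, _ = identity_pair
        frame = rows_to_frame([compare_cases(case_a, case_b)])
        assert list(frame.columns) == [
            "case_id", "sop_uid", "slice", "phase", "contour", "position",
            "segmented_a", "segmented_b", "dice", "hd_mm", "ml_diff",
            "abs_ml_diff"]
        assert len(frame) == len(compare_cases(case_a, case_b).rows)
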