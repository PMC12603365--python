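"""Outcome-rule derivation: cutoffs, dysphagia, END, recovery, imputation."""

import numpy as np
import pytest

import strokemap as sm
from strokemap.cohort import NIHSS_ITEMS, NIHSSExam
from strokemap.cohort_derivation import (
    classify_end_cause,
    derive_dysphagia,
    derive_end,
    derive_recovery,
    dichotomize_tmt,
    impute_infarct_volume,
    max_total_increment,
)

from conftest import random_exam_series


def exam_from_totals(totals, t_step=1.0, item="4", second_item="9"):
    """Exam series realizing the given totals on non-motor, non-consciousness
    items (so only the total-increment criteria can fire)."""
    exams = []
    for i, tot in enumerate(totals):
        items = {k: 0 for k in NIHSS_ITEMS}
        a = min(tot, NIHSS_ITEMS[item])
        items[item] = a
        rem = tot - a
        items[second_item] = min(rem, NIHSS_ITEMS[second_item])
        rem -= items[second_item]
        for k in ("10", "8", "2", "3", "7", "11"):
            take = min(rem, NIHSS_ITEMS[k])
            items[k] = take
            rem -= take
        assert rem == 0, f"cannot realize total {tot} on non-motor items"
        exams.append(NIHSSExam(t_days=i * t_step, items=items))
    return exams


class TestDichotomize:
    def test_linear_interpolation_quartile(self):
        spec, low = dichotomize_tmt([1.0, 2.0, 3.0, 4.0])
        assert spec.value == pytest.approx(1.75)
        assert list(low) == [True, False, False, False]
        assert spec.method == "linear"

    def test_fraction_below_cutoff_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(1.8, 0.3, size=10_000)
        spec, low = dichotomize_tmt(vals)
        # brute-force oracle: sort and read off the interpolated quartile
        s = np.sort(vals)
        k = 0.25 * (len(s) - 1)
        lo, hi = int(np.floor(k)), int(np.ceil(k))
        oracle = s[lo] + (k - lo) * (s[hi] - s[lo])
        assert spec.value == pytest.approx(oracle)
        assert 0.24 <= low.mean() <= 0.26

    def test_ties_go_to_high_group(self):
        spec, low = dichotomize_tmt([5.0, 5.0, 5.0, 9.0])
        assert not low[0]  # strictly-below rule

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="indices"):
            dichotomize_tmt([5.0, -1.0, 6.0])


class TestDysphagia:
    @pytest.mark.parametrize("fois,expected", [(7, False), (6, True), (1, True)])
    def test_fois_rule(self, fois, expected):
        assert derive_dysphagia(fois) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            derive_dysphagia(0)


class TestEnd:
    def test_flat_totals_no_end(self):
        end, end4 = derive_end(exam_from_totals([4, 4, 4]), False)
        assert (end, end4) == (False, False)

    def test_total_increment_of_two(self):
        # item 3 cannot rise by 2 within its max, use item 4 (max 3)
        exams = exam_from_totals([4, 6])
        end, end4 = derive_end(exams, False)
        assert (end, end4) == (True, False)

    def test_motor_criterion_single_point(self):
        base = {k: 0 for k in NIHSS_ITEMS}
        base["5a"], base["9"] = 1, 3
        worse = dict(base)
        worse["5a"] = 2
        exams = [NIHSSExam(0.0, base), NIHSSExam(2.0, worse)]
        end, end4 = derive_end(exams, False)
        assert (end, end4) == (True, False)  # via motor, total rose only 1

    def test_consciousness_criterion(self):
        base = {k: 0 for k in NIHSS_ITEMS}
        worse = dict(base)
        worse["1a"] = 1
        end, _ = derive_end([NIHSSExam(0.0, base), NIHSSExam(1.0, worse)], False)
        assert end

    def test_running_minimum_reference(self):
        # decline then rebound: 10 -> 3 -> 7 rises 4 above the running min
        end, end4 = derive_end(exam_from_totals([10, 3, 7]), False)
        assert (end, end4) == (True, True)

    def test_admission_reference_misses_rebound(self):
        end, end4 = derive_end(exam_from_totals([10, 3, 7]), False, reference="admission")
        assert (end, end4) == (False, False)

    def test_new_deficit_flag_alone(self):
        end, end4 = derive_end(exam_from_totals([4, 4]), True)
        assert (end, end4) == (True, False)

    def test_exams_only_after_window_rejected(self):
        items = {k: 0 for k in NIHSS_ITEMS}
        with pytest.raises(ValueError, match="window"):
            derive_end([NIHSSExam(25.0, items)], False)

    def test_event_outside_window_ignored(self):
        exams = exam_from_totals([4, 4])
        late = exam_from_totals([9])[0]
        late = NIHSSExam(t_days=28.0, items=late.items)
        end, _ = derive_end(exams + [late], False)
        assert not end

    def test_oracle_equivalence_on_random_trajectories(self):
        """Running-minimum END equals brute-force enumeration over all
        ordered exam pairs, on 1000 random trajectories."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            exams = random_exam_series(rng)
            flag = bool(rng.integers(0, 2))
            end, end4 = derive_end(exams, flag)
            win = [e for e in exams if e.t_days <= 21.0]
            if not win:
                continue
            o_end = flag
            o_end4 = False
            for i in range(len(win)):
                for j in range(i + 1, len(win)):
                    if win[j].total - win[i].total >= 2:
                        o_end = True
                    if win[j].total - win[i].total >= 4:
                        o_end4 = True
                    if win[j].consciousness - win[i].consciousness >= 1:
                        o_end = True
                    if win[j].motor - win[i].motor >= 1:
                        o_end = True
            assert (end, end4) == (o_end, o_end4)

    def test_monotone_in_added_worsening_exam(self):
        """Appending a later exam with a higher total never clears END."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            exams = [e for e in random_exam_series(rng) if e.t_days < 20.5]
            if not exams:
                continue
            end_before, _ = derive_end(exams, False)
            worst = max(e.total for e in exams)
            extra_items = {k: 0 for k in NIHSS_ITEMS}
            budget = min(worst + 2, sum(NIHSS_ITEMS.values()))
            for k in NIHSS_ITEMS:
                take = min(budget, NIHSS_ITEMS[k])
                extra_items[k] = take
                budget -= take
            exams2 = exams + [NIHSSExam(t_days=20.5, items=extra_items)]
            end_after, _ = derive_end(exams2, False)
            assert not (end_before and not end_after)


class TestEndCause:
    def _record(self, totals, cause):
        exams = exam_from_totals(totals)
        return sm.PatientRecord(
            subject_id="X", age=70, sex="male", height=170, weight=70,
            tmt_left=6, tmt_right=6, pre_mrs=0, previous_stroke=False,
            hypertension=False, diabetes=False, hyperlipidaemia=False,
            smoking=False, atrial_fibrillation=False,
            coronary_artery_disease=False, stroke_subtype="LAA",
            revascularization=False, haemoglobin=14, total_cholesterol=170,
            albumin=4.2, fois=7, nihss_exams=exams, mrs_discharge=2,
            mrs_3mo=2, mrs_1y=2, end_cause_label=cause,
        )

    def test_non_end_maps_to_none(self):
        cause, warn = classify_end_cause(self._record([4, 4], "progression"), False)
        assert cause == "none" and not warn

    def test_sht_with_big_increment_clean(self):
        cause, warn = classify_end_cause(self._record([4, 9], "sHT"), True)
        assert cause == "sHT" and not warn

    def test_sht_without_increment_warns_but_keeps_label(self):
        cause, warn = classify_end_cause(self._record([4, 6], "sHT"), True)
        assert cause == "sHT" and warn

    def test_max_increment_uses_running_min(self):
        assert max_total_increment(exam_from_totals([10, 3, 7])) == 4


class TestRecovery:
    def _record(self, adm, dis, mrs_dis=3, mrs3=3, mrs1y=3):
        exams = exam_from_totals([adm, dis], t_step=7.0)
        return sm.PatientRecord(
            subject_id="X", age=70, sex="male", height=170, weight=70,
            tmt_left=6, tmt_right=6, pre_mrs=0, previous_stroke=False,
            hypertension=False, diabetes=False, hyperlipidaemia=False,
            smoking=False, atrial_fibrillation=False,
            coronary_artery_disease=False, stroke_subtype="LAA",
            revascularization=False, haemoglobin=14, total_cholesterol=170,
            albumin=4.2, fois=7, nihss_exams=exams, mrs_discharge=mrs_dis,
            mrs_3mo=mrs3, mrs_1y=mrs1y,
        )

    def test_four_point_improvement(self):
        assert derive_recovery(self._record(10, 6))["inhosp_recovery"] is True

    def test_forty_percent_boundary_exact(self):
        assert derive_recovery(self._record(5, 3))["inhosp_recovery"] is True

    def test_below_both_thresholds(self):
        assert derive_recovery(self._record(10, 7))["inhosp_recovery"] is False

    def test_admission_zero_ineligible(self):
        assert derive_recovery(self._record(0, 0))["inhosp_recovery"] is None

    def test_postdischarge_strict_inequality(self):
        r = self._record(10, 6, mrs_dis=3, mrs3=3)
        assert derive_recovery(r)["postdischarge_recovery"] is False

    @pytest.mark.parametrize("mrs_dis", [0, 6])
    def test_postdischarge_ineligible_boundaries(self, mrs_dis):
        r = self._record(10, 6, mrs_dis=mrs_dis, mrs3=min(mrs_dis, 5))
        assert derive_recovery(r)["postdischarge_recovery"] is None

    def test_chronic_requires_1y_followup(self):
        r = self._record(10, 6, mrs3=3, mrs1y=None)
        assert derive_recovery(r)["chronic_recovery"] is None

    def test_chronic_improvement(self):
        r = self._record(10, 6, mrs3=3, mrs1y=2)
        assert derive_recovery(r)["chronic_recovery"] is True


class TestImputation:
    def test_median_fills_missing(self):
        out, n, med = impute_infarct_volume([0.1, np.nan, 0.3])
        assert out[1] == pytest.approx(0.2) and n == 1 and med == pytest.approx(0.2)

    def test_identity_when_complete(self):
        out, n, _ = impute_infarct_volume([0.1, 0.2])
        assert n == 0 and list(out) == [0.1, 0.2]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_infarct_volume([np.nan, np.nan])


class TestCohortLevel:
    def test_eligibility_partitions(self, frame600):
        """Eligible + excluded = cohort size for each recovery period."""
        df, sidecar = frame600
        n = len(df)
        for col, key in [
            ("inhosp_recovery", "inhosp_admission_nihss_0"),
            ("postdischarge_recovery", "postdischarge_mrs_0_or_6"),
            ("chronic_recovery", "chronic_mrs3_0_or_6_or_lost"),
        ]:
            assert df[col].notna().sum() + sidecar["exclusions"][key] == n

    def test_low_tmt_fraction_near_quartile(self, frame600):
        df, _ = frame600
        assert abs(df["low_tmt"].mean() - 0.25) <= 2 / len(df)

    def test_end_cause_none_iff_no_end(self, frame600):
        df, _ = frame600
        assert ((df["end_cause"] == "none") == ~df["end"]).all()

    def test_dysphagia_consistent_with_fois(self, cohort600, frame600):
        df, _ = frame600
        fois = np.array([r.fois for r in cohort600])
        assert (df["dysphagia"].to_numpy() == (fois <= 6)).all()
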