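"""Rule-based derivation of analysis-ready outcomes and exposures.

This module turns raw registry records into the flags the association
models consume:

* **Low TMT** — mean of the left and right temporal-muscle-thickness
  measurements, dichotomized at the cohort 25th percentile (strictly
  below the cutoff = low).  The same rule applies to TMT normalized by
  height squared.
* **Dysphagia** — Functional Oral Intake Scale 1-6 (7 = unrestricted
  oral intake).
* **END (early neurological deterioration)** — any of, within 3 weeks of
  onset: total NIHSS increment >= 2; consciousness subscore (items
  1a-1c) increment >= 1; motor subscore (items 5a-6b) increment >= 1; or
  any new neurological deficit recorded clinically.  END_4 is the
  stricter >= 4-point total increment.  Increments are measured against
  the running minimum of preceding exams by default (equivalently: over
  all ordered exam pairs), because deterioration after early improvement
  is still deterioration; comparison against the admission exam only is
  available as an option.
* **Recovery** in three periods, each with its eligibility rule:
  in-hospital (NIHSS improvement >= 4 points or >= 40% admission to
  discharge; admission NIHSS 0 ineligible), post-discharge (3-month mRS
  strictly below discharge mRS; discharge mRS 0 or 6 ineligible) and
  chronic (1-year mRS strictly below 3-month mRS; 3-month mRS 0 or 6, or
  missing 1-year mRS, ineligible).

Ineligible is represented as missing (None/NaN), distinct from False.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .cohort import NIHSSExam, PatientRecord

logger = logging.getLogger(__name__)

END_WINDOW_DAYS = 21.0


@dataclass(frozen=True)
class CutoffSpec:
    """A percentile cutoff computed on the full analysis cohort."""

    variable: str  # "tmt_mean" | "tmt_h2"
    percentile: float
    method: str  # numpy quantile convention identifier
    value: float

    def to_dict(self) -> dict:
        return asdict(self)


def dichotomize_tmt(
    values, variable: str = "tmt_mean", percentile: float = 25.0, method: str = "linear"
) -> tuple[CutoffSpec, np.ndarray]:
    """25th-percentile dichotomization of a muscle-thickness variable.

    Returns the cutoff (with its quantile convention made explicit) and a
    boolean low-flag vector: ``low = value < cutoff``, so ties at the
    cutoff fall in the high group.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("values must be a nonempty 1-D array")
    bad = np.where(~np.isfinite(arr) | (arr <= 0))[0]
    if len(bad):
        raise ValueError(f"nonpositive or missing {variable} at indices {bad.tolist()}")
    cutoff = float(np.quantile(arr, percentile / 100.0, method=method))
    spec = CutoffSpec(variable=variable, percentile=percentile, method=method, value=cutoff)
    return spec, arr < cutoff


def derive_dysphagia(fois: int) -> bool:
    """Dysphagia = restricted oral intake, FOIS 1-6 (7 is normal)."""
    if not (1 <= int(fois) <= 7):
        raise ValueError(f"FOIS {fois} outside 1..7")
    return int(fois) <= 6


def derive_end(
    exams: list[NIHSSExam],
    new_deficit_flag: bool,
    window_days: float = END_WINDOW_DAYS,
    reference: str = "running_min",
) -> tuple[bool, bool]:
    """(END, END_4) from a time-sorted exam series.

    ``reference="running_min"`` measures each exam's increment against
    the minimum of all preceding exams (separately for the total and for
    the consciousness and motor subscores); ``reference="admission"``
    measures against the first exam only.
    """
    if reference not in ("running_min", "admission"):
        raise ValueError(f"unknown reference {reference!r}")
    ts = [e.t_days for e in exams]
    if ts != sorted(ts):
        raise ValueError("exams must be time-sorted")
    in_window = [e for e in exams if e.t_days <= window_days]
    if not in_window:
        raise ValueError("no NIHSS exam within the deterioration window")

    end = bool(new_deficit_flag)
    end4 = False
    ref_total = in_window[0].total
    ref_cons = in_window[0].consciousness
    ref_motor = in_window[0].motor
    for e in in_window[1:]:
        if e.total - ref_total >= 2:
            end = True
        if e.total - ref_total >= 4:
            end4 = True
        if e.consciousness - ref_cons >= 1:
            end = True
        if e.motor - ref_motor >= 1:
            end = True
        if reference == "running_min":
            ref_total = min(ref_total, e.total)
            ref_cons = min(ref_cons, e.consciousness)
            ref_motor = min(ref_motor, e.motor)
    return end, end4


def max_total_increment(
    exams: list[NIHSSExam], window_days: float = END_WINDOW_DAYS
) -> int:
    """Largest total-NIHSS rise over any ordered exam pair in the window."""
    totals = [e.total for e in exams if e.t_days <= window_days]
    best = 0
    run_min = totals[0] if totals else 0
    for t in totals[1:]:
        best = max(best, t - run_min)
        run_min = min(run_min, t)
    return best


def classify_end_cause(record: PatientRecord, end_flag: bool) -> tuple[str, bool]:
    """Pass through the clinical END-cause label, validating the sHT rule.

    Symptomatic haemorrhagic transformation requires a >= 4-point NIHSS
    rise; a sHT label without one is kept but flagged as a discrepancy.
    Non-END subjects map to ``"none"``.  Returns (category, warning).
    """
    if not end_flag:
        return "none", False
    label = record.end_cause_label
    warn = False
    if label == "sHT" and max_total_increment(record.nihss_exams) < 4:
        warn = True
        logger.warning(
            "subject %s: sHT label without a >=4-point NIHSS increment", record.subject_id
        )
    return label, warn


def derive_recovery(record: PatientRecord) -> dict[str, bool | None]:
    """Period-specific recovery flags; None marks ineligibility.

    The >= 40% in-hospital criterion is evaluated with exact rational
    arithmetic on the integer NIHSS scores.
    """
    out: dict[str, bool | None] = {}

    adm = record.admission_nihss
    dis = record.discharge_nihss
    if adm == 0:
        out["inhosp_recovery"] = None
    else:
        improvement = adm - dis
        out["inhosp_recovery"] = bool(
            improvement >= 4 or Fraction(improvement, adm) >= Fraction(2, 5)
        )

    if record.mrs_discharge in (0, 6):
        out["postdischarge_recovery"] = None
    else:
        out["postdischarge_recovery"] = bool(record.mrs_3mo < record.mrs_discharge)

    if record.mrs_3mo in (0, 6) or record.mrs_1y is None:
        out["chronic_recovery"] = None
    else:
        out["chronic_recovery"] = bool(record.mrs_1y < record.mrs_3mo)

    return out


def impute_infarct_volume(values) -> tuple[np.ndarray, int, float]:
    """Median-impute missing infarct volumes.

    Returns (imputed values, number imputed, median used).
    """
    arr = np.asarray(values, dtype=float)
    missing = ~np.isfinite(arr)
    if missing.all():
        raise ValueError("all infarct volumes missing; cannot impute")
    med = float(np.median(arr[~missing]))
    n_imputed = int(missing.sum())
    out = arr.copy()
    out[missing] = med
    return out, n_imputed, med


def derive_outcomes(
    cohort: list[PatientRecord],
    end_reference: str = "running_min",
) -> tuple[pd.DataFrame, dict]:
    """Full per-subject derived-outcome table plus a metadata sidecar.

    The returned frame is keyed by ``subject_id`` and contains the
    exposure dichotomies, outcome flags (NaN where ineligible or lost to
    follow-up) and the imputed infarct volume.  The sidecar dict records
    both cutoffs, eligibility-exclusion tallies and the imputation count.
    """
    if not cohort:
        raise ValueError("empty cohort")
    tmt = [r.tmt_mean for r in cohort]
    tmt_h2 = [r.tmt_h2 for r in cohort]
    cut_tmt, low_tmt = dichotomize_tmt(tmt, "tmt_mean")
    cut_h2, low_h2 = dichotomize_tmt(tmt_h2, "tmt_h2")
    vol_imp, n_imputed, vol_median = impute_infarct_volume(
        [np.nan if r.infarct_volume_pct is None else r.infarct_volume_pct for r in cohort]
    )

    rows = []
    warnings = 0
    for i, r in enumerate(cohort):
        end, end4 = derive_end(r.nihss_exams, r.new_deficit_within_3w, reference=end_reference)
        cause, warned = classify_end_cause(r, end)
        warnings += warned
        rec = derive_recovery(r)
        row = {
            "subject_id": r.subject_id,
            "tmt_mean": r.tmt_mean,
            "low_tmt": bool(low_tmt[i]),
            "tmt_h2": r.tmt_h2,
            "low_tmt_h2": bool(low_h2[i]),
            "dysphagia": derive_dysphagia(r.fois),
            "end": end,
            "end4": end4,
            "end_cause": cause,
            "motor_deficit": r.nihss_exams[0].motor >= 1,
            "inhosp_recovery": rec["inhosp_recovery"],
            "postdischarge_recovery": rec["postdischarge_recovery"],
            "chronic_recovery": rec["chronic_recovery"],
            "mrs3_ge3": r.mrs_3mo >= 3,
            "mrs3_ge4": r.mrs_3mo >= 4,
            "mrs1y_ge3": None if r.mrs_1y is None else r.mrs_1y >= 3,
            "mrs1y_ge4": None if r.mrs_1y is None else r.mrs_1y >= 4,
            "infarct_volume_pct_imputed": vol_imp[i],
        }
        rows.append(row)
    derived = pd.DataFrame(rows)
    for col in ("inhosp_recovery", "postdischarge_recovery", "chronic_recovery",
                "mrs1y_ge3", "mrs1y_ge4"):
        derived[col] = derived[col].astype("float")  # None -> NaN, bool -> 0/1

    sidecar = {
        "cutoff_tmt": cut_tmt.to_dict(),
        "cutoff_tmt_h2": cut_h2.to_dict(),
        "n_subjects": len(cohort),
        "n_low_tmt": int(low_tmt.sum()),
        "exclusions": {
            "inhosp_admission_nihss_0": int(derived["inhosp_recovery"].isna().sum()),
            "postdischarge_mrs_0_or_6": int(derived["postdischarge_recovery"].isna().sum()),
            "chronic_mrs3_0_or_6_or_lost": int(derived["chronic_recovery"].isna().sum()),
            "lost_to_1y_followup": int(derived["mrs1y_ge3"].isna().sum()),
        },
        "infarct_volume_imputations": n_imputed,
        "infarct_volume_median": vol_median,
        "sht_label_discrepancies": warnings,
        "end_reference": end_reference,
    }
    return derived, sidecar


def analysis_frame(cohort: list[PatientRecord], end_reference: str = "running_min") -> tuple[pd.DataFrame, dict]:
    """Subjects frame merged with derived outcomes, ready for modelling."""
    from .cohort import cohort_to_frames

    subjects, _ = cohort_to_frames(cohort)
    subjects["admission_nihss"] = [r.admission_nihss for r in cohort]
    subjects["discharge_nihss"] = [r.discharge_nihss for r in cohort]
    derived, sidecar = derive_outcomes(cohort, end_reference=end_reference)
    merged = subjects.merge(derived, on="subject_id", validate="1:1")
    return merged, sidecar
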