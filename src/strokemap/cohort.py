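"""Patient-record data model and CSV round-tripping.

A cohort is a list of :class:`PatientRecord` objects.  On disk it is two
plain CSVs: one row per subject for the registry variables, plus a
long-format companion table of serial NIHSS exams keyed by ``subject_id``
and ``t_days``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

#: NIHSS items in standard order with their legal maxima.
NIHSS_ITEMS: dict[str, int] = {
    "1a": 3, "1b": 2, "1c": 2, "2": 2, "3": 3, "4": 3,
    "5a": 4, "5b": 4, "6a": 4, "6b": 4,
    "7": 2, "8": 2, "9": 3, "10": 2, "11": 2,
}

CONSCIOUSNESS_ITEMS = ("1a", "1b", "1c")
MOTOR_ITEMS = ("5a", "5b", "6a", "6b")

STROKE_SUBTYPES = ("LAA", "SVO", "CE", "undetermined", "other")
END_CAUSES = ("progression", "recurrence", "TIA", "sHT", "others", "unknown", "none")


@dataclass(frozen=True)
class NIHSSExam:
    """One itemized NIHSS examination at ``t_days`` from stroke onset."""

    t_days: float
    items: dict[str, int]

    def __post_init__(self) -> None:
        if self.t_days < 0:
            raise ValueError("t_days must be >= 0")
        if set(self.items) != set(NIHSS_ITEMS):
            missing = set(NIHSS_ITEMS) - set(self.items)
            extra = set(self.items) - set(NIHSS_ITEMS)
            raise ValueError(f"bad NIHSS item set (missing {missing}, extra {extra})")
        for k, v in self.items.items():
            if not (0 <= v <= NIHSS_ITEMS[k]):
                raise ValueError(f"item {k} = {v} outside 0..{NIHSS_ITEMS[k]}")

    @property
    def total(self) -> int:
        return sum(self.items.values())

    @property
    def consciousness(self) -> int:
        return sum(self.items[k] for k in CONSCIOUSNESS_ITEMS)

    @property
    def motor(self) -> int:
        return sum(self.items[k] for k in MOTOR_ITEMS)


@dataclass
class PatientRecord:
    """One subject's registry row."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    tmt_left: float  # mm
    tmt_right: float  # mm
    pre_mrs: int  # 0 or 1 (scores >= 2 excluded upstream)
    previous_stroke: bool
    hypertension: bool
    diabetes: bool
    hyperlipidaemia: bool
    smoking: bool
    atrial_fibrillation: bool
    coronary_artery_disease: bool
    stroke_subtype: str
    revascularization: bool
    haemoglobin: float  # g/dL
    total_cholesterol: float  # mg/dL
    albumin: float  # g/dL
    fois: int  # 1..7
    nihss_exams: list[NIHSSExam] = field(default_factory=list)
    mrs_discharge: int = 0
    mrs_3mo: int = 0
    mrs_1y: int | None = None  # None = lost to 1-year follow-up
    new_deficit_within_3w: bool = False
    end_cause_label: str = "none"
    infarct_volume_pct: float | None = None  # % of brain volume
    lesion_mask_ref: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.tmt_left <= 0 or self.tmt_right <= 0:
            raise ValueError(f"subject {self.subject_id}: TMT must be positive")
        if not (1 <= self.fois <= 7):
            raise ValueError(f"subject {self.subject_id}: FOIS {self.fois} outside 1..7")
        for name in ("mrs_discharge", "mrs_3mo"):
            v = getattr(self, name)
            if not (0 <= v <= 6):
                raise ValueError(f"subject {self.subject_id}: {name} {v} outside 0..6")
        if self.mrs_1y is not None and not (0 <= self.mrs_1y <= 6):
            raise ValueError(f"subject {self.subject_id}: mrs_1y outside 0..6")
        if self.pre_mrs not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: pre_mrs must be 0 or 1")
        if self.stroke_subtype not in STROKE_SUBTYPES:
            raise ValueError(f"unknown stroke subtype {self.stroke_subtype!r}")
        if self.end_cause_label not in END_CAUSES:
            raise ValueError(f"unknown END cause {self.end_cause_label!r}")
        if self.nihss_exams:
            ts = [e.t_days for e in self.nihss_exams]
            if ts != sorted(ts):
                raise ValueError(f"subject {self.subject_id}: NIHSS exams not time-sorted")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    @property
    def tmt_mean(self) -> float:
        return (self.tmt_left + self.tmt_right) / 2.0

    @property
    def tmt_h2(self) -> float:
        """TMT normalized by height squared, mm/m^2."""
        return self.tmt_mean / (self.height / 100.0) ** 2

    @property
    def admission_nihss(self) -> int:
        if not self.nihss_exams:
            raise ValueError(f"subject {self.subject_id}: no NIHSS exams")
        return self.nihss_exams[0].total

    @property
    def discharge_nihss(self) -> int:
        if not self.nihss_exams:
            raise ValueError(f"subject {self.subject_id}: no NIHSS exams")
        return self.nihss_exams[-1].total


_SCALAR_FIELDS = [
    f.name for f in fields(PatientRecord) if f.name not in ("nihss_exams",)
]


def cohort_to_frames(cohort: list[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(subjects frame, long-format NIHSS exam frame)."""
    rows = []
    exam_rows = []
    for r in cohort:
        row = {name: getattr(r, name) for name in _SCALAR_FIELDS}
        row["bmi"] = r.bmi
        rows.append(row)
        for e in r.nihss_exams:
            exam_rows.append({"subject_id": r.subject_id, "t_days": e.t_days, **e.items})
    subjects = pd.DataFrame(rows)
    exams = pd.DataFrame(exam_rows, columns=["subject_id", "t_days", *NIHSS_ITEMS])
    return subjects, exams


def frames_to_cohort(subjects: pd.DataFrame, exams: pd.DataFrame) -> list[PatientRecord]:
    exam_map: dict[str, list[NIHSSExam]] = {}
    for sid, grp in exams.groupby("subject_id", sort=False):
        grp = grp.sort_values("t_days")
        exam_map[str(sid)] = [
            NIHSSExam(
                t_days=float(row["t_days"]),
                items={k: int(row[k]) for k in NIHSS_ITEMS},
            )
            for _, row in grp.iterrows()
        ]
    cohort = []
    bool_fields = {
        "previous_stroke", "hypertension", "diabetes", "hyperlipidaemia",
        "smoking", "atrial_fibrillation", "coronary_artery_disease",
        "revascularization", "new_deficit_within_3w",
    }
    for _, row in subjects.iterrows():
        kw = {}
        for name in _SCALAR_FIELDS:
            v = row[name]
            if name in bool_fields:
                v = bool(v)
            elif name in ("mrs_1y", "infarct_volume_pct"):
                v = None if pd.isna(v) else (int(v) if name == "mrs_1y" else float(v))
            elif name == "lesion_mask_ref":
                v = None if pd.isna(v) else str(v)
            elif name in ("fois", "pre_mrs", "mrs_discharge", "mrs_3mo"):
                v = int(v)
            elif name in ("subject_id", "sex", "stroke_subtype", "end_cause_label"):
                v = str(v)
            else:
                v = float(v)
            kw[name] = v
        kw["nihss_exams"] = exam_map.get(str(row["subject_id"]), [])
        cohort.append(PatientRecord(**kw))
    return cohort


def write_cohort_csv(cohort: list[PatientRecord], subjects_path: str | Path, exams_path: str | Path) -> None:
    subjects, exams = cohort_to_frames(cohort)
    subjects.to_csv(subjects_path, index=False)
    exams.to_csv(exams_path, index=False)


def read_cohort_csv(subjects_path: str | Path, exams_path: str | Path) -> list[PatientRecord]:
    subjects = pd.read_csv(subjects_path)
    exams = pd.read_csv(exams_path)
    exams.columns = [str(c) for c in exams.columns]
    return frames_to_cohort(subjects, exams)
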