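"""Synthetic stroke-cohort and lesion-image generator.

Produces registry-style patient records with the statistical structure
the downstream analysis assumes: Table-1-like covariate marginals (an
elderly cohort, mean age ~75, half male, temporal muscle thickness lower
in women and decreasing with age), event rates near the observed ones,
and *planted* exposure/mediator/outcome effects expressed as log-odds
coefficients, so parameter-recovery and power tests are well-posed.

Outcomes are drawn top-down from logistic models and the raw record
fields (FOIS, serial NIHSS exams, the mRS trajectory) are then
constructed to be exactly consistent with the drawn flags, so that the
rule-based derivation recovers the planted binary variables without
error.  Lesions are contiguous random voxel blobs on a toy template with
toy left/right-homologous atlases.

All randomness flows from one integer seed, expanded into independent
substreams (covariates, outcomes/trajectories, lesions) so that changing
one stage leaves the others bit-identical.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit, logit

from .cohort import MOTOR_ITEMS, NIHSS_ITEMS, NIHSSExam, PatientRecord

# ---------------------------------------------------------------------------
# Defaults: the study conditions the generator emulates


def _ln(x: float) -> float:
    return math.log(x)


#: Linear-predictor coefficients (log-odds) of the planted outcome models.
#: Keys are ``outcome|term``.  Exposure effects default to the adjusted
#: odds ratios the analysis is designed to recover; intercepts set the
#: approximate unexposed event rates; the small covariate slopes create
#: genuine confounding through age and severity.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "dysphagia|intercept": logit(0.17),
    "dysphagia|low_tmt": _ln(1.89),
    "dysphagia|admission_nihss": 0.12,
    "dysphagia|age10": 0.30,
    "end|intercept": logit(0.12),
    "end|low_tmt": _ln(2.75),
    "end|admission_nihss": 0.08,
    "end|infarct_pct": 0.10,
    "end4_given_end|intercept": logit(0.36),
    "end4_given_end|low_tmt": 0.0,
    "inhosp_recovery|intercept": logit(0.47),
    "inhosp_recovery|low_tmt": _ln(0.67),
    "postdischarge_recovery|intercept": logit(0.36),
    "postdischarge_recovery|low_tmt": _ln(0.56),
    "chronic_recovery|intercept": logit(0.27),
    "chronic_recovery|low_tmt": 0.0,
    "mrs3_ge3|intercept": logit(0.20),
    "mrs3_ge3|low_tmt": _ln(1.60),
    "mrs3_ge3|dysphagia": _ln(2.00),
    "mrs3_ge3|end": _ln(2.50),
    "mrs3_ge3|postdischarge_recovery": _ln(0.45),
    "mrs3_ge3|admission_nihss": 0.18,
    "mrs3_ge3|age10": 0.40,
    "mrs3_ge3|infarct_pct": 0.08,
}

#: Covariate marginals (means/SDs/proportions).  Sex-specific means make
#: height, smoking and haemoglobin differ by sex; TMT is a linear model
#: in sex and age plus Gaussian noise truncated at 1 mm.
DEFAULT_COVARIATE_PARAMS: dict = {
    "male_prop": 0.505,
    "age_mean": 75.3,
    "age_sd": 6.1,
    "age_min": 65.0,
    "height_mean_male": 166.0,
    "height_mean_female": 152.0,
    "height_sd": 6.0,
    "bmi_mean": 23.9,
    "bmi_sd": 3.3,
    "tmt_intercept": 5.99,  # at age 75.3, female
    "tmt_male_shift": 1.40,
    "tmt_age_slope": -0.08,  # mm per year
    "tmt_sd": 1.92,
    "tmt_min": 1.0,
    "pre_mrs1_prop": 0.12,
    "previous_stroke_prop": 0.198,
    "hypertension_prop": 0.827,
    "diabetes_prop": 0.447,
    "hyperlipidaemia_prop": 0.522,
    "smoking_prop_male": 0.75,
    "smoking_prop_female": 0.11,
    "atrial_fibrillation_prop": 0.233,
    "coronary_artery_disease_prop": 0.095,
    "subtype_props": {
        "LAA": 0.352,
        "SVO": 0.253,
        "CE": 0.183,
        "undetermined": 0.208,
        "other": 0.004,
    },
    "revascularization_prop": 0.103,
    "haemoglobin_mean_male": 14.3,
    "haemoglobin_mean_female": 12.5,
    "haemoglobin_sd": 1.5,
    "total_cholesterol_mean": 170.3,
    "total_cholesterol_sd": 39.3,
    "albumin_mean": 4.2,
    "albumin_sd": 0.4,
    "nihss_zero_prop": 0.087,
    "nihss_log_mean": _ln(4.0),
    "nihss_log_sd": 0.814,
    "infarct_log_median": _ln(0.07),
    "infarct_log_sd": 2.26,
    "infarct_max_pct": 30.0,
    "infarct_missing_prop": 2.0 / 600.0,
}

DEFAULT_LESION_PARAMS: dict = {
    "grid": (20, 20, 20),  # voxels per axis
    "voxel_volume_mm3": 8.0,
    "blob_count": 1,
    "blob_size_median": 20.0,  # voxels
    "blob_size_log_sd": 1.0,
    "blob_size_max": 800,
}


@dataclass
class SimulationConfig:
    """Complete description of one simulated study."""

    n_subjects: int = 600
    seed: int = 0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    covariate_params: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COVARIATE_PARAMS)
    )
    lesion_params: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_LESION_PARAMS)
    )
    followup_loss_rate_1y: float = 20.0 / 600.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects >= 1):
            raise ValueError(f"n_subjects must be a positive integer, got {self.n_subjects}")
        if not (0.0 <= self.followup_loss_rate_1y <= 1.0):
            raise ValueError(
                f"followup_loss_rate_1y must be in [0,1], got {self.followup_loss_rate_1y}"
            )
        for key, val in self.covariate_params.items():
            if key.endswith("_sd") and not val > 0:
                raise ValueError(f"covariate_params[{key!r}] must be > 0, got {val}")
            if key.endswith("_prop") and not (0.0 <= val <= 1.0):
                raise ValueError(f"covariate_params[{key!r}] must be in [0,1], got {val}")
        props = self.covariate_params.get("subtype_props", {})
        if props and not math.isclose(sum(props.values()), 1.0, abs_tol=0.05):
            raise ValueError("covariate_params['subtype_props'] must sum to ~1")
        grid = tuple(self.lesion_params.get("grid", ()))
        if len(grid) != 3 or any(g < 8 for g in grid):
            raise ValueError(f"lesion_params['grid'] must have 3 axes each >= 8, got {grid}")
        if not self.lesion_params.get("voxel_volume_mm3", 1.0) > 0:
            raise ValueError("lesion_params['voxel_volume_mm3'] must be > 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def pyify(obj):
            if isinstance(obj, dict):
                return {k: pyify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [pyify(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                return float(obj)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            return obj

        d = {
            "n_subjects": int(self.n_subjects),
            "seed": int(self.seed),
            "effect_sizes": pyify(self.effect_sizes),
            "covariate_params": pyify(self.covariate_params),
            "lesion_params": pyify(self.lesion_params),
            "followup_loss_rate_1y": float(self.followup_loss_rate_1y),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = copy.deepcopy(d)
        if "lesion_params" in d and "grid" in d["lesion_params"]:
            d["lesion_params"]["grid"] = tuple(d["lesion_params"]["grid"])
        base = cls(n_subjects=d.get("n_subjects", 600), seed=d.get("seed", 0))
        base.effect_sizes.update(d.get("effect_sizes", {}))
        base.covariate_params.update(d.get("covariate_params", {}))
        base.lesion_params.update(d.get("lesion_params", {}))
        base.followup_loss_rate_1y = d.get("followup_loss_rate_1y", base.followup_loss_rate_1y)
        base.validate()
        return base

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def null_config(n_subjects: int = 600, seed: int = 0) -> SimulationConfig:
    """A configuration with every exposure/mediator/direct effect zeroed
    (intercepts and covariate slopes retained)."""
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed)
    for key in cfg.effect_sizes:
        outcome_term = key.split("|")[1]
        if outcome_term not in ("intercept",):
            if outcome_term in ("low_tmt", "dysphagia", "end", "postdischarge_recovery"):
                cfg.effect_sizes[key] = 0.0
    return cfg


# ---------------------------------------------------------------------------
# Cohort simulation


def _allocate_nihss(total: int, rng: np.random.Generator) -> dict[str, int]:
    """Distribute a target total over the 15 items, respecting maxima.

    Motor items carry the largest weights so that motor deficits are the
    most common presenting symptom, as in real stroke cohorts.
    """
    weights = {
        "1a": 0.03, "1b": 0.03, "1c": 0.03, "2": 0.05, "3": 0.04, "4": 0.09,
        "5a": 0.15, "5b": 0.15, "6a": 0.13, "6b": 0.13,
        "7": 0.03, "8": 0.05, "9": 0.07, "10": 0.09, "11": 0.03,
    }
    keys = list(weights)
    w = np.array([weights[k] for k in keys])
    maxima = np.array([NIHSS_ITEMS[k] for k in keys])
    counts = np.zeros(len(keys), dtype=int)
    remaining = int(total)
    # vectorized draw, redistributing any overflow past per-item maxima
    while remaining > 0:
        open_ = counts < maxima
        if not open_.any():
            break
        p = np.where(open_, w, 0.0)
        p /= p.sum()
        picks = np.bincount(rng.choice(len(keys), size=remaining, p=p), minlength=len(keys))
        new = np.minimum(counts + picks, maxima)
        remaining -= int((new - counts).sum())
        counts = new
    return {k: int(c) for k, c in zip(keys, counts)}


def _remove_points(items: dict[str, int], n: int, rng: np.random.Generator) -> dict[str, int]:
    out = dict(items)
    for _ in range(n):
        pos = [k for k, v in out.items() if v > 0]
        if not pos:
            break
        out[rng.choice(pos)] -= 1
    return out


def _add_points(
    items: dict[str, int], n: int, rng: np.random.Generator, prefer: tuple[str, ...] = ()
) -> dict[str, int]:
    out = dict(items)
    for _ in range(n):
        cand = [k for k in prefer if out[k] < NIHSS_ITEMS[k]]
        if not cand:
            cand = [k for k in NIHSS_ITEMS if out[k] < NIHSS_ITEMS[k]]
        if not cand:
            break
        out[rng.choice(cand)] += 1
    return out


def _lp(effects: dict[str, float], outcome: str, terms: dict[str, np.ndarray]) -> np.ndarray:
    """Assemble a linear predictor from ``outcome|term`` coefficients."""
    n = len(next(iter(terms.values())))
    lp = np.zeros(n)
    for key, coef in effects.items():
        out, term = key.split("|")
        if out != outcome or coef == 0.0:
            continue
        if term == "intercept":
            lp = lp + coef
        else:
            if term not in terms:
                raise KeyError(f"effect {key!r} references unknown term {term!r}")
            lp = lp + coef * terms[term]
    return lp


def simulate_cohort(config: SimulationConfig, return_truth: bool = False):
    """Draw a full cohort of patient records.

    Reproducible for a fixed seed.  The low-TMT exposure used to plant
    effects is defined exactly as the analysis defines it: strictly below
    the in-sample 25th percentile of mean TMT.

    With ``return_truth=True`` also returns a DataFrame of the drawn
    (ground-truth) binary flags per subject, so tests can check that the
    rule-based derivation reproduces the planted variables exactly.
    """
    config.validate()
    cp = config.covariate_params
    es = config.effect_sizes
    n = config.n_subjects
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_out, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    # --- covariates -------------------------------------------------------
    male = rng_cov.random(n) < cp["male_prop"]
    age = cp["age_mean"] + cp["age_sd"] * rng_cov.standard_normal(n)
    # reflect draws below the eligibility floor (cohort is >= 65 years)
    age = np.where(age < cp["age_min"], 2 * cp["age_min"] - age, age)
    height = np.where(male, cp["height_mean_male"], cp["height_mean_female"])
    height = height + cp["height_sd"] * rng_cov.standard_normal(n)
    bmi = np.clip(cp["bmi_mean"] + cp["bmi_sd"] * rng_cov.standard_normal(n), 13.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    tmt_mean = (
        cp["tmt_intercept"]
        + cp["tmt_male_shift"] * male
        + cp["tmt_age_slope"] * (age - cp["age_mean"])
        + cp["tmt_sd"] * rng_cov.standard_normal(n)
    )
    tmt_mean = np.maximum(tmt_mean, cp["tmt_min"])
    side_jitter = 0.1 * rng_cov.standard_normal(n)
    tmt_left = np.maximum(tmt_mean - side_jitter, 0.2)
    tmt_right = np.maximum(2.0 * tmt_mean - tmt_left, 0.2)

    pre_mrs = (rng_cov.random(n) < cp["pre_mrs1_prop"]).astype(int)
    prev_stroke = rng_cov.random(n) < cp["previous_stroke_prop"]
    htn = rng_cov.random(n) < cp["hypertension_prop"]
    dm = rng_cov.random(n) < cp["diabetes_prop"]
    lipid = rng_cov.random(n) < cp["hyperlipidaemia_prop"]
    smoking = rng_cov.random(n) < np.where(
        male, cp["smoking_prop_male"], cp["smoking_prop_female"]
    )
    af = rng_cov.random(n) < cp["atrial_fibrillation_prop"]
    cad = rng_cov.random(n) < cp["coronary_artery_disease_prop"]
    subtype_levels = list(cp["subtype_props"])
    subtype_p = np.array([cp["subtype_props"][k] for k in subtype_levels], dtype=float)
    subtype_p = subtype_p / subtype_p.sum()
    subtype = rng_cov.choice(subtype_levels, size=n, p=subtype_p)
    revasc = rng_cov.random(n) < cp["revascularization_prop"]
    hgb = np.where(male, cp["haemoglobin_mean_male"], cp["haemoglobin_mean_female"])
    hgb = hgb + cp["haemoglobin_sd"] * rng_cov.standard_normal(n)
    chol = cp["total_cholesterol_mean"] + cp["total_cholesterol_sd"] * rng_cov.standard_normal(n)
    chol = np.maximum(chol, 60.0)
    alb = cp["albumin_mean"] + cp["albumin_sd"] * rng_cov.standard_normal(n)

    nihss0 = rng_cov.random(n) < cp["nihss_zero_prop"]
    adm_nihss = np.round(
        np.exp(cp["nihss_log_mean"] + cp["nihss_log_sd"] * rng_cov.standard_normal(n))
    ).astype(int)
    adm_nihss = np.clip(adm_nihss, 1, 40)
    adm_nihss[nihss0] = 0

    infarct = np.exp(
        cp["infarct_log_median"] + cp["infarct_log_sd"] * rng_cov.standard_normal(n)
    )
    infarct = np.minimum(infarct, cp["infarct_max_pct"])
    infarct_missing = rng_cov.random(n) < cp["infarct_missing_prop"]

    # --- exposure: low TMT at the in-sample 25th percentile ---------------
    cutoff = np.quantile(tmt_mean, 0.25, method="linear")
    low_tmt = (tmt_mean < cutoff).astype(float)

    terms = {
        "low_tmt": low_tmt,
        "admission_nihss": adm_nihss - 4.0,
        "age10": (age - cp["age_mean"]) / 10.0,
        # linear in infarct burden, matching the form the analysis adjusts
        "infarct_pct": infarct - 0.07,
    }

    # --- mediators and outcomes ------------------------------------------
    dysphagia = rng_out.random(n) < expit(_lp(es, "dysphagia", terms))
    end = rng_out.random(n) < expit(_lp(es, "end", terms))
    end4 = end & (rng_out.random(n) < expit(_lp(es, "end4_given_end", terms)))
    ih_draw = rng_out.random(n) < expit(_lp(es, "inhosp_recovery", terms))
    m3_draw = rng_out.random(n) < expit(_lp(es, "postdischarge_recovery", terms))
    terms_y = dict(terms)
    terms_y["dysphagia"] = dysphagia.astype(float)
    terms_y["end"] = end.astype(float)
    terms_y["postdischarge_recovery"] = m3_draw.astype(float)
    y3 = rng_out.random(n) < expit(_lp(es, "mrs3_ge3", terms_y))
    chronic_draw = rng_out.random(n) < expit(_lp(es, "chronic_recovery", terms))
    lost_1y = rng_out.random(n) < config.followup_loss_rate_1y

    records: list[PatientRecord] = []
    for i in range(n):
        # mRS trajectory consistent with (y3, m3_draw)
        if y3[i]:
            if m3_draw[i]:
                mrs3 = int(rng_out.choice([3, 4], p=[0.55, 0.45]))
            else:
                mrs3 = int(rng_out.choice([3, 4, 5, 6], p=[0.42, 0.33, 0.17, 0.08]))
        else:
            mrs3 = int(rng_out.choice([0, 1, 2], p=[0.18, 0.45, 0.37]))
        if m3_draw[i] and mrs3 <= 4:
            mrs_dis = mrs3 + int(rng_out.choice([1, 2], p=[0.7, 0.3]))
            mrs_dis = min(mrs_dis, 5)
        elif mrs3 == 6:
            mrs_dis = int(rng_out.choice([4, 5, 6], p=[0.3, 0.3, 0.4]))
        else:
            if rng_out.random() < 0.85 or mrs3 == 0:
                mrs_dis = mrs3
            else:
                mrs_dis = mrs3 - 1
        # chronic period
        if mrs3 == 6:
            mrs1y: int | None = 6
        elif mrs3 == 0:
            mrs1y = 0 if rng_out.random() < 0.9 else 1
        elif chronic_draw[i]:
            mrs1y = mrs3 - 1
        else:
            mrs1y = mrs3 if rng_out.random() < 0.85 else min(mrs3 + 1, 6)
        if lost_1y[i]:
            mrs1y = None

        # NIHSS trajectory consistent with (end, end4, ih_draw)
        adm = int(adm_nihss[i])
        adm_items = _allocate_nihss(adm, rng_out)
        exams = [NIHSSExam(t_days=0.0, items=adm_items)]
        new_deficit = False
        if adm == 0:
            d = 0
        else:
            t_min = min(4, -(-2 * adm // 5))  # smallest qualifying improvement
            if ih_draw[i]:
                d = int(rng_out.integers(t_min, adm + 1))
            else:
                d = int(rng_out.integers(0, t_min))
        if end[i]:
            t_event = float(rng_out.integers(1, 15))
            if end4[i]:
                inc = int(rng_out.integers(4, 7))
                event_items = _add_points(
                    adm_items, inc, rng_out, prefer=MOTOR_ITEMS + ("1a", "4", "10")
                )
            else:
                mech = rng_out.choice(
                    ["total2", "motor1", "consciousness1", "new_deficit"],
                    p=[0.55, 0.25, 0.10, 0.10],
                )
                if mech == "total2":
                    inc = int(rng_out.integers(2, 4))
                    event_items = _add_points(adm_items, inc, rng_out, prefer=MOTOR_ITEMS)
                elif mech == "motor1":
                    event_items = _add_points(adm_items, 1, rng_out, prefer=MOTOR_ITEMS)
                elif mech == "consciousness1":
                    event_items = _add_points(adm_items, 1, rng_out, prefer=("1a", "1b", "1c"))
                else:
                    event_items = dict(adm_items)
                    new_deficit = True
                if sum(event_items.values()) - adm >= 4:
                    # maxima forced the increment elsewhere; trim to keep END_4 false
                    event_items = _remove_points(
                        event_items, sum(event_items.values()) - adm - 2, rng_out
                    )
            exams.append(NIHSSExam(t_days=t_event, items=event_items))
            t_dis = t_event + float(rng_out.integers(3, 8))
            removal = sum(event_items.values()) - (adm - d)
            dis_items = _remove_points(event_items, max(removal, 0), rng_out)
        else:
            t_dis = float(rng_out.integers(4, 15))
            dis_items = _remove_points(adm_items, d, rng_out)
        exams.append(NIHSSExam(t_days=t_dis, items=dis_items))

        # END cause labels; sHT only where the >=4-point rule holds
        if end[i] and end4[i] and sum(event_items.values()) - adm < 4:
            # item maxima capped the planted rise (near-maximal admission
            # severity): demote so derived END_4 stays consistent
            end4[i] = False
        if end[i]:
            if end4[i]:
                cause = str(
                    rng_out.choice(
                        ["progression", "sHT", "recurrence", "others", "unknown", "TIA"],
                        p=[0.70, 0.15, 0.03, 0.04, 0.07, 0.01],
                    )
                )
            elif new_deficit:
                cause = str(
                    rng_out.choice(["progression", "recurrence", "others", "unknown"],
                                   p=[0.55, 0.10, 0.15, 0.20])
                )
            else:
                cause = str(
                    rng_out.choice(
                        ["progression", "recurrence", "others", "unknown", "TIA"],
                        p=[0.80, 0.03, 0.04, 0.12, 0.01],
                    )
                )
        else:
            cause = "none"

        fois = int(rng_out.integers(1, 7)) if dysphagia[i] else 7

        records.append(
            PatientRecord(
                subject_id=f"S{i:05d}",
                age=float(age[i]),
                sex="male" if male[i] else "female",
                height=float(height[i]),
                weight=float(weight[i]),
                tmt_left=float(tmt_left[i]),
                tmt_right=float(tmt_right[i]),
                pre_mrs=int(pre_mrs[i]),
                previous_stroke=bool(prev_stroke[i]),
                hypertension=bool(htn[i]),
                diabetes=bool(dm[i]),
                hyperlipidaemia=bool(lipid[i]),
                smoking=bool(smoking[i]),
                atrial_fibrillation=bool(af[i]),
                coronary_artery_disease=bool(cad[i]),
                stroke_subtype=str(subtype[i]),
                revascularization=bool(revasc[i]),
                haemoglobin=float(hgb[i]),
                total_cholesterol=float(chol[i]),
                albumin=float(alb[i]),
                fois=fois,
                nihss_exams=exams,
                mrs_discharge=mrs_dis,
                mrs_3mo=mrs3,
                mrs_1y=mrs1y,
                new_deficit_within_3w=new_deficit,
                end_cause_label=cause,
                infarct_volume_pct=None if infarct_missing[i] else float(infarct[i]),
            )
        )
    if return_truth:
        import pandas as pd

        truth = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in records],
                "low_tmt": low_tmt.astype(bool),
                "dysphagia": dysphagia,
                "end": end,
                "end4": end4,
                "inhosp_recovery": ih_draw,
                "postdischarge_recovery": m3_draw,
                "mrs3_ge3": y3,
                "chronic_recovery": chronic_draw,
            }
        )
        return records, truth
    return records


# ---------------------------------------------------------------------------
# Lesion simulation


def _grow_blob(
    shape: tuple[int, int, int],
    brain: np.ndarray,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Contiguous random blob grown from a seeded voxel (6-connectivity)."""
    mask = np.zeros(shape, dtype=bool)
    brain_idx = np.argwhere(brain)
    seed = tuple(int(c) for c in brain_idx[rng.integers(len(brain_idx))])
    offsets = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))

    def neighbours(v):
        for o in offsets:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and brain[w]
            ):
                yield w

    mask[seed] = True
    grown = 1
    cand_list = []
    cand_set = set()
    for w in neighbours(seed):
        cand_list.append(w)
        cand_set.add(w)
    while grown < size and cand_list:
        i = int(rng.integers(len(cand_list)))
        v = cand_list[i]
        cand_list[i] = cand_list[-1]
        cand_list.pop()
        cand_set.discard(v)
        mask[v] = True
        grown += 1
        for w in neighbours(v):
            if not mask[w] and w not in cand_set:
                cand_list.append(w)
                cand_set.add(w)
    return mask


def make_toy_atlases(lesion_params: dict):
    """Toy atlas stack on the template grid.

    Three atlases mimicking the merge problem: a midline brainstem-like
    atlas (highest priority), a cortical parcellation with left/right
    homologues, and a white-matter tract atlas whose slabs overlap both.
    Returns a list of :class:`~strokemap.brain_mapping.Atlas` in priority
    order, plus the template brain mask.
    """
    from .brain_mapping import Atlas

    nx, ny, nz = tuple(lesion_params["grid"])
    brain = np.ones((nx, ny, nz), dtype=bool)

    def frac(a, lo, hi):
        return slice(int(round(a * lo)), int(round(a * hi)))

    mid = nx // 2

    bs = np.zeros((nx, ny, nz), dtype=np.int16)
    bs[frac(nx, 0.4, 0.6), frac(ny, 0.4, 0.6), frac(nz, 0.0, 0.18)] = 1  # lower brainstem
    bs[frac(nx, 0.4, 0.6), frac(ny, 0.4, 0.6), frac(nz, 0.18, 0.35)] = 2  # pons-like
    bs_table = [(1, "brainstem_lower", "mid"), (2, "pons_like", "mid")]

    cort = np.zeros((nx, ny, nz), dtype=np.int16)
    cort[: mid, frac(ny, 0.55, 1.0), frac(nz, 0.5, 1.0)] = 1  # frontal_L
    cort[mid:, frac(ny, 0.55, 1.0), frac(nz, 0.5, 1.0)] = 2  # frontal_R
    cort[: mid, frac(ny, 0.0, 0.45), frac(nz, 0.5, 1.0)] = 3  # parietal_L
    cort[mid:, frac(ny, 0.0, 0.45), frac(nz, 0.5, 1.0)] = 4  # parietal_R
    cort[: mid, frac(ny, 0.3, 0.7), frac(nz, 0.3, 0.5)] = 5  # deep_L
    cort[mid:, frac(ny, 0.3, 0.7), frac(nz, 0.3, 0.5)] = 6  # deep_R
    cort_table = [
        (1, "frontal_L", "L"), (2, "frontal_R", "R"),
        (3, "parietal_L", "L"), (4, "parietal_R", "R"),
        (5, "deep_L", "L"), (6, "deep_R", "R"),
    ]

    tract = np.zeros((nx, ny, nz), dtype=np.int16)
    tract[frac(nx, 0.15, 0.35), frac(ny, 0.35, 0.6), frac(nz, 0.1, 0.75)] = 1  # cst_L
    tract[frac(nx, 0.65, 0.85), frac(ny, 0.35, 0.6), frac(nz, 0.1, 0.75)] = 2  # cst_R
    tract[frac(nx, 0.15, 0.35), frac(ny, 0.6, 0.85), frac(nz, 0.2, 0.6)] = 3  # fpt_L
    tract[frac(nx, 0.65, 0.85), frac(ny, 0.6, 0.85), frac(nz, 0.2, 0.6)] = 4  # fpt_R
    tract_table = [
        (1, "cst_L", "L"), (2, "cst_R", "R"),
        (3, "fpt_L", "L"), (4, "fpt_R", "R"),
    ]

    def table(entries):
        import pandas as pd

        return pd.DataFrame(entries, columns=["label", "name", "hemisphere"])

    atlases = [
        Atlas(name="brainstem", labels=bs, label_table=table(bs_table)),
        Atlas(name="cortical", labels=cort, label_table=table(cort_table)),
        Atlas(name="tract", labels=tract, label_table=table(tract_table)),
    ]
    return atlases, brain


def simulate_lesions(cohort: list[PatientRecord], config: SimulationConfig):
    """Per-subject binary lesion masks plus a merged toy atlas set.

    Each mask is one contiguous blob grown from a random seed voxel.
    ``infarct_volume_pct`` is recomputed from the mask for every subject
    that receives one; subjects whose registry infarct volume is missing
    model the "no DWI" case and get no mask.  Modifies the cohort in
    place and returns ``(masks, atlas_set)``.
    """
    from .brain_mapping import merge_atlases

    config.validate()
    lp = config.lesion_params
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    shape = tuple(lp["grid"])
    atlases, brain = make_toy_atlases(lp)
    atlas_set = merge_atlases(
        atlases,
        priority=[a.name for a in atlases],
        voxel_volume_mm3=lp["voxel_volume_mm3"],
        brain_mask=brain,
    )
    n_brain = int(brain.sum())
    masks: dict[str, np.ndarray] = {}
    for rec in cohort:
        if rec.infarct_volume_pct is None:
            rec.lesion_mask_ref = None
            continue
        size = int(
            round(
                math.exp(
                    math.log(lp["blob_size_median"])
                    + lp["blob_size_log_sd"] * rng.standard_normal()
                )
            )
        )
        size = int(np.clip(size, 1, min(lp["blob_size_max"], n_brain)))
        mask = np.zeros(shape, dtype=bool)
        for _ in range(int(lp.get("blob_count", 1))):
            mask |= _grow_blob(shape, brain, size, rng)
        masks[rec.subject_id] = mask
        rec.lesion_mask_ref = rec.subject_id
        rec.infarct_volume_pct = float(mask.sum()) / n_brain * 100.0
    return masks, atlas_set


def planted_lesion_outcome(
    df,
    burden,
    roi_effects: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    exposure: str = "low_tmt",
    intercept: float = -0.8,
    exposure_beta: float = 0.4,
    nihss_beta: float = 0.10,
) -> np.ndarray:
    """Binary outcome with planted per-ROI lesion and lesion-by-exposure
    effects, for power and false-positive-rate studies.

    ``roi_effects`` maps ROI column names to ``(beta_lesion,
    beta_interaction)`` log-odds per 1% of brain lesioned in that ROI.
    """
    n = len(df)
    expo = df[exposure].to_numpy(dtype=float)
    lp = intercept + exposure_beta * expo + nihss_beta * (
        df["admission_nihss"].to_numpy(dtype=float) - 4.0
    )
    for roi, (b_lesion, b_inter) in roi_effects.items():
        b = burden[roi].reindex(df["subject_id"]).to_numpy(dtype=float)
        lp = lp + b_lesion * b + b_inter * b * expo
    return (rng.random(n) < expit(lp)).astype(float)
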