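"""End-to-end orchestration: derive, estimate, decompose, map, report.

``run_pipeline`` composes the library stages into one reproducible run:
outcome derivation -> crude 2x2 effects -> covariate-adjusted models ->
symptom/lesion interaction scans -> mediation -> ROI brain mapping ->
sensitivity analyses (continuous TMT per 1 mm decrease; TMT/height^2).
Every run writes tidy CSV tables plus a machine-readable JSON manifest
(inputs, seed, cutoffs, exclusion tallies) sufficient to reproduce it
bit-identically.

``table_fixtures`` packages the published 2x2 outcome tables of the
original 600-patient cohort (low-TMT vs high-TMT event counts with the
footnoted eligibility exclusions applied); they serve as deterministic
regression fixtures for the crude-effects code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PatientRecord, write_cohort_csv
from .cohort_derivation import analysis_frame
from .effects import (
    ContingencyTable2x2,
    adjusted_effect,
    interaction_scan,
    odds_ratio_2x2,
)
from .mediation import MediationSpec, mediate, mediator_entry_screen
from .synthetic_cohort import SimulationConfig, simulate_cohort, simulate_lesions

logger = logging.getLogger(__name__)

#: Outcomes analysed crudely and adjusted, with direction of interest.
PRIMARY_OUTCOMES = (
    "dysphagia",
    "end",
    "inhosp_recovery",
    "postdischarge_recovery",
    "chronic_recovery",
    "mrs3_ge3",
    "mrs3_ge4",
    "mrs1y_ge3",
    "mrs1y_ge4",
)


def table_fixtures() -> dict[str, ContingencyTable2x2]:
    """The nine published low-vs-high-TMT outcome tables.

    Cells are (exposed events, exposed non-events, unexposed events,
    unexposed non-events); denominators already reflect the
    period-specific eligibility exclusions (admission NIHSS 0 for
    in-hospital recovery; discharge mRS 0/6 post-discharge; 3-month mRS
    0/6 or 1-year loss to follow-up for the chronic period and 1-year
    outcomes).
    """
    counts = {
        "dysphagia": (55, 151 - 55, 90, 449 - 90),
        "end": (43, 151 - 43, 63, 449 - 63),
        "inhosp_recovery": (46, 138 - 46, 191, 410 - 191),
        "postdischarge_recovery": (31, 139 - 31, 138, 400 - 138),
        "chronic_recovery": (30, 124 - 30, 101, 367 - 101),
        "mrs3_ge3": (91, 151 - 91, 150, 449 - 150),
        "mrs3_ge4": (56, 151 - 56, 61, 449 - 61),
        "mrs1y_ge3": (78, 140 - 78, 130, 440 - 130),
        "mrs1y_ge4": (50, 140 - 50, 67, 440 - 67),
    }
    return {k: ContingencyTable2x2(*v) for k, v in counts.items()}


def crude_effects_table(df: pd.DataFrame, exposure: str = "low_tmt") -> pd.DataFrame:
    """Table-2/3-style crude summary: per-outcome counts, percentages and
    univariable odds ratios with Woolf 95% CIs."""
    rows = []
    for outcome in PRIMARY_OUTCOMES:
        if outcome not in df.columns:
            continue
        sub = df.dropna(subset=[outcome])
        e = sub[exposure].astype(bool)
        y = sub[outcome].astype(float)
        a = int(y[e].sum())
        b = int((1 - y[e]).sum())
        c = int(y[~e].sum())
        d = int((1 - y[~e]).sum())
        est = odds_ratio_2x2(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "outcome": outcome,
                "exposed_events": a,
                "exposed_n": a + b,
                "exposed_pct": 100.0 * a / (a + b) if a + b else np.nan,
                "unexposed_events": c,
                "unexposed_n": c + d,
                "unexposed_pct": 100.0 * c / (c + d) if c + d else np.nan,
                "or": est.or_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
            }
        )
    return pd.DataFrame(rows)


def adjusted_effects_table(
    df: pd.DataFrame,
    exposure: str = "low_tmt",
    outcomes=PRIMARY_OUTCOMES,
    method: str = "ml",
    per_unit_decrease: bool = False,
) -> pd.DataFrame:
    rows = []
    for outcome in outcomes:
        if outcome not in df.columns:
            continue
        try:
            est, fit = adjusted_effect(
                df, exposure, outcome, method=method, per_unit_decrease=per_unit_decrease
            )
        except ValueError as exc:
            logger.warning("adjusted model for %s failed: %s", outcome, exc)
            continue
        rows.append(
            {
                "outcome": outcome,
                "exposure": exposure,
                "aor": est.or_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
                "method": fit.method,
                "n": fit.n_obs,
                "events": fit.n_events,
                "scale": est.scale_note,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Inputs, toggles and the master seed for one full run."""

    output_dir: str | Path = "strokemap_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    cohort_csv: str | Path | None = None
    exams_csv: str | Path | None = None
    run_crude: bool = True
    run_adjusted: bool = True
    run_scans: bool = True
    run_mediation: bool = True
    run_mapping: bool = True
    run_sensitivity: bool = True
    mediation_n_boot: int = 200
    end_reference: str = "running_min"

    def __post_init__(self) -> None:
        if self.simulation is None and self.cohort_csv is None:
            raise ValueError("either a simulation config or a cohort CSV is required")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Stage failures are recorded in the manifest and already-written
    outputs are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "strokemap_version": __version__,
        "seed": int(config.seed),
        "stages": {},
        "outputs": [],
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    # --- load or simulate -------------------------------------------------
    masks = atlas_set = None
    if config.simulation is not None:
        sim = config.simulation
        sim.seed = int(config.seed)
        cohort: list[PatientRecord] = simulate_cohort(sim)
        if config.run_mapping:
            masks, atlas_set = simulate_lesions(cohort, sim)
        write_cohort_csv(cohort, out / "cohort.csv", out / "nihss_exams.csv")
        manifest["outputs"] += ["cohort.csv", "nihss_exams.csv"]
        manifest["input"] = {"simulation": sim.to_dict()}
    else:
        from .cohort import read_cohort_csv

        cohort = read_cohort_csv(config.cohort_csv, config.exams_csv)
        manifest["input"] = {
            "cohort_csv": str(config.cohort_csv),
            "exams_csv": str(config.exams_csv),
        }

    df, sidecar = analysis_frame(cohort, end_reference=config.end_reference)
    manifest["derivation"] = sidecar
    _write(df, "analysis_frame.csv")

    def _stage(name: str, fn) -> None:
        if not getattr(config, f"run_{name}", True):
            manifest["stages"][name] = "skipped"
            return
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:  # stage isolation: keep partial outputs
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = f"failed: {exc}"

    _stage("crude", lambda: _write(crude_effects_table(df), "crude_effects.csv"))
    _stage("adjusted", lambda: _write(adjusted_effects_table(df), "adjusted_effects.csv"))

    def _scans() -> None:
        results = interaction_scan(
            df, "low_tmt", "mrs3_ge3", modifiers=["motor_deficit"]
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "modifier": r.modifier,
                        "or_absent": r.or_modifier_absent,
                        "or_present": r.or_modifier_present,
                        "p_interaction": r.p_interaction,
                        "method": r.method,
                    }
                    for r in results
                ]
            ),
            "interaction_scan.csv",
        )

    _stage("scans", _scans)

    def _mediation() -> None:
        candidates = ["dysphagia", "end", "postdischarge_recovery", "chronic_recovery"]
        admitted, screen = mediator_entry_screen(df, candidates)
        _write(screen, "mediator_screen.csv")
        if not admitted:
            logger.warning("no mediators admitted; skipping decomposition")
            return
        spec = MediationSpec(
            mediators=admitted, n_boot=config.mediation_n_boot, seed=int(config.seed)
        )
        result = mediate(df, spec)
        _write(result.to_frame(), "mediation.csv")
        manifest["mediation"] = {
            "admitted": admitted,
            "proportion_mediated": result.proportion_mediated,
        }

    _stage("mediation", _mediation)

    def _mapping() -> None:
        if masks is None or atlas_set is None:
            logger.warning("no lesion masks available; mapping skipped")
            return
        from .brain_mapping import interaction_table, map_interactions, roi_burden

        burden = roi_burden(masks, atlas_set)
        burden.to_csv(out / "roi_burden.csv")
        manifest["outputs"].append("roi_burden.csv")
        results = map_interactions(df, burden, outcome="mrs3_ge3")
        _write(interaction_table(results), "roi_interactions.csv")

    _stage("mapping", _mapping)

    def _sensitivity() -> None:
        cont = adjusted_effects_table(
            df, exposure="tmt_mean", per_unit_decrease=True
        )
        h2 = adjusted_effects_table(df, exposure="low_tmt_h2")
        _write(pd.concat([cont, h2], ignore_index=True), "sensitivity_effects.csv")

    _stage("sensitivity", _sensitivity)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
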