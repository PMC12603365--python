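"""ROI-wise effect-modification mapping on lesion masks.

Merges several labelled atlases into one parcellation by a stated
priority order, quantifies each subject's lesion burden per merged ROI
(as % of total brain volume), fits one logistic interaction model per
ROI — lesion burden, exposure, their product and the clinical covariates
(total infarct volume excluded for collinearity with the ROI burden) —
and reports regions whose lesion-by-exposure interaction is significant
at p < 0.05.  No multiple-comparison correction is applied; that is a
deliberate, documented default.

Symmetric left/right ROI pairs can be pooled (burdens summed) to gain
power for bilateral effects.

All volumes live in voxel-index space on one shared grid with one shared
affine; inputs on a different grid are rejected, not resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .effects import (
    DEFAULT_COVARIATES,
    SeparationError,
    build_design,
    fit_logistic,
)

logger = logging.getLogger(__name__)

#: ROIs with fewer lesioned subjects than this are fitted with the Firth
#: penalty and flagged low-support rather than skipped.
LOW_SUPPORT_N = 5


@dataclass
class Atlas:
    """One labelled volume: integer labels plus a label table
    (columns ``label``, ``name``, ``hemisphere``)."""

    name: str
    labels: np.ndarray
    label_table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas {self.name}: labels must be a 3-D volume")
        required = {"label", "name"}
        if not required <= set(self.label_table.columns):
            raise ValueError(f"atlas {self.name}: label table needs columns {required}")


@dataclass
class AtlasSet:
    """Priority-merged parcellation sharing one grid and voxel size."""

    atlases: list[Atlas]
    priority: list[str]
    merged: np.ndarray  # integer ROI ids, 0 = unlabeled
    label_table: pd.DataFrame  # roi_id, roi_name, atlas, source_label, hemisphere
    voxel_volume_mm3: float
    brain_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def roi_names(self) -> list[str]:
        return self.label_table["roi_name"].tolist()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.merged.astype(np.int16), self.affine),
            directory / "merged_atlas.nii",
        )
        nib.save(
            nib.Nifti1Image(self.brain_mask.astype(np.uint8), self.affine),
            directory / "brain_mask.nii",
        )
        self.label_table.to_csv(directory / "label_table.csv", index=False)


def merge_atlases(
    atlases: list[Atlas],
    priority: list[str],
    voxel_volume_mm3: float,
    brain_mask: np.ndarray,
    affine: np.ndarray | None = None,
) -> AtlasSet:
    """Merge label volumes so each voxel keeps the label of the
    highest-priority atlas claiming it.

    ``priority`` lists atlas names from highest to lowest priority and
    must have no duplicates.  Merged ROI ids are new consecutive
    integers; provenance (atlas, source label) is retained in the label
    table.  Voxels claimed by no atlas stay unlabeled (0).
    """
    if len(set(priority)) != len(priority):
        raise ValueError("priority order contains duplicates")
    by_name = {a.name: a for a in atlases}
    if set(priority) != set(by_name):
        raise ValueError("priority must name exactly the provided atlases")
    shape = atlases[0].labels.shape
    affine = atlases[0].affine if affine is None else affine
    for a in atlases:
        if a.labels.shape != shape:
            raise ValueError(f"atlas {a.name}: grid {a.labels.shape} != {shape}")
        if not np.allclose(a.affine, affine):
            raise ValueError(f"atlas {a.name}: affine mismatch")
    if brain_mask.shape != shape:
        raise ValueError("brain mask grid mismatch")

    merged = np.zeros(shape, dtype=np.int32)
    rows = []
    next_id = 1
    # lowest priority first so higher-priority atlases overwrite
    for name in reversed(priority):
        atlas = by_name[name]
        for _, row in atlas.label_table.iterrows():
            src = int(row["label"])
            voxels = atlas.labels == src
            if not voxels.any():
                continue
            merged[voxels] = next_id
            rows.append(
                {
                    "roi_id": next_id,
                    "roi_name": row["name"],
                    "atlas": name,
                    "source_label": src,
                    "hemisphere": row.get("hemisphere", ""),
                }
            )
            next_id += 1
    table = pd.DataFrame(rows)
    # drop ROIs entirely overwritten by higher-priority atlases
    present = np.unique(merged)
    table = table[table["roi_id"].isin(present)].reset_index(drop=True)
    return AtlasSet(
        atlases=atlases,
        priority=list(priority),
        merged=merged,
        label_table=table,
        voxel_volume_mm3=float(voxel_volume_mm3),
        brain_mask=np.asarray(brain_mask, dtype=bool),
        affine=np.asarray(affine, dtype=float),
    )


def roi_burden(masks: dict[str, np.ndarray], atlas: AtlasSet) -> pd.DataFrame:
    """Lesion burden per subject and merged ROI, as % of brain volume.

    Returns a frame indexed by subject id with one column per ROI name
    plus ``total`` (overall lesion % against the template brain mask).
    Row sums over ROIs never exceed the total; they are equal exactly
    when every lesioned voxel carries a label.
    """
    n_brain = int(atlas.brain_mask.sum())
    if n_brain == 0:
        raise ValueError("empty template brain mask")
    ids = atlas.label_table["roi_id"].to_numpy()
    names = atlas.label_table["roi_name"].tolist()
    rows = {}
    for sid, mask in masks.items():
        mask = np.asarray(mask)
        if mask.shape != atlas.merged.shape:
            raise ValueError(f"subject {sid}: mask grid {mask.shape} off the atlas grid")
        mask = mask.astype(bool)
        labels_hit = atlas.merged[mask]
        counts = np.bincount(labels_hit, minlength=int(ids.max()) + 1 if len(ids) else 1)
        row = {name: counts[i] / n_brain * 100.0 for i, name in zip(ids, names)}
        row["total"] = mask[atlas.brain_mask].sum() / n_brain * 100.0
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out[names + ["total"]] if rows else pd.DataFrame(columns=names + ["total"])


def pool_symmetric(burden: pd.DataFrame, pairing: dict[str, str]) -> pd.DataFrame:
    """Pool left/right symmetric ROI columns by summing burdens.

    ``pairing`` maps a left ROI name to its right homologue; midline
    ROIs may map to themselves.  A ROI appearing in two pairs is
    rejected.  Pooled columns are named ``name_pooled`` with the
    hemisphere suffix stripped.
    """
    seen: set[str] = set()
    for left, right in pairing.items():
        members = {left, right}
        if members & seen:
            raise ValueError(f"ROI in multiple pairs: {members & seen}")
        seen |= members
    for roi in seen:
        if roi not in burden.columns:
            raise ValueError(f"pairing references unknown ROI {roi!r}")
    out = {}
    for left, right in pairing.items():
        base = left
        for suffix in ("_L", "_left", "_l"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
                break
        name = f"{base}_pooled"
        out[name] = (
            burden[left] if left == right else burden[left] + burden[right]
        )
    pooled = pd.DataFrame(out, index=burden.index)
    if "total" in burden.columns:
        pooled["total"] = burden["total"]
    return pooled


@dataclass
class ROIInteractionResult:
    roi: str
    beta_lesion: float
    beta_exposure: float
    beta_interaction: float
    p_interaction: float
    n_lesioned: int
    method: str
    significant: bool
    low_support: bool = False


def map_interactions(
    df: pd.DataFrame,
    burden: pd.DataFrame,
    outcome: str,
    exposure: str = "low_tmt",
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> list[ROIInteractionResult]:
    """Per-ROI lesion-by-exposure interaction models.

    Each model contains the ROI lesion burden, the exposure, their
    product and the clinical covariates, with total infarct volume
    removed from the covariate list (collinear with ROI burden).
    Subjects without a lesion mask (absent from ``burden``) are excluded.
    ROIs with no lesioned subject are skipped; ROIs with fewer than
    ``LOW_SUPPORT_N`` lesioned subjects are fitted with the Firth
    penalty and flagged low-support.
    """
    covs = list(DEFAULT_COVARIATES if covariates is None else covariates)
    covs = [c for c in covs if c not in ("infarct_volume_pct_imputed", exposure, outcome)]
    data = df[df["subject_id"].isin(burden.index)].dropna(subset=[outcome]).copy()
    if data.empty:
        raise ValueError("no subjects with both a lesion mask and the outcome")
    aligned = burden.reindex(data["subject_id"])
    y = data[outcome].to_numpy(dtype=float)
    expo = data[exposure].to_numpy(dtype=float)
    X_cov, cov_names = build_design(data, [exposure] + covs)

    results: list[ROIInteractionResult] = []
    rois = [c for c in burden.columns if c != "total"]
    for roi in rois:
        b = aligned[roi].to_numpy(dtype=float)
        n_lesioned = int((b > 0).sum())
        if n_lesioned == 0:
            logger.warning("ROI %s: no lesioned subjects; skipped", roi)
            continue
        X = np.column_stack([X_cov, b, b * expo])
        names = cov_names + [f"burden[{roi}]", f"{exposure}:burden[{roi}]"]
        low_support = n_lesioned < LOW_SUPPORT_N
        method = "firth" if low_support else "ml"
        try:
            fit = fit_logistic(X, y, method=method, term_names=names)
            if fit.separation_detected:
                raise SeparationError("quasi-separation in ROI model")
        except SeparationError:
            method = "firth"
            fit = fit_logistic(X, y, method=method, term_names=names)
        wald = fit.wald().set_index("term")
        inter = f"{exposure}:burden[{roi}]"
        if inter not in wald.index:  # aliased (e.g. constant burden)
            logger.warning("ROI %s: interaction term aliased; skipped", roi)
            continue
        p_int = float(wald.loc[inter, "p"])
        results.append(
            ROIInteractionResult(
                roi=roi,
                beta_lesion=float(wald.loc[f"burden[{roi}]", "beta"])
                if f"burden[{roi}]" in wald.index
                else float("nan"),
                beta_exposure=float(wald.loc[exposure, "beta"]),
                beta_interaction=float(wald.loc[inter, "beta"]),
                p_interaction=p_int,
                n_lesioned=n_lesioned,
                method=fit.method,
                significant=bool(p_int < alpha),
                low_support=low_support,
            )
        )
    return results


def interaction_table(results: list[ROIInteractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": r.roi,
                "beta_lesion": r.beta_lesion,
                "beta_exposure": r.beta_exposure,
                "beta_interaction": r.beta_interaction,
                "p_interaction": r.p_interaction,
                "n_lesioned": r.n_lesioned,
                "method": r.method,
                "significant": r.significant,
                "low_support": r.low_support,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_masks(masks: dict[str, np.ndarray], directory: str | Path, affine=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    for sid, mask in masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), directory / f"{sid}.nii")


def load_masks(directory: str | Path) -> dict[str, np.ndarray]:
    directory = Path(directory)
    masks = {}
    for path in sorted(directory.glob("*.nii*")):
        sid = path.name.split(".nii")[0]
        masks[sid] = np.asarray(nib.load(path).dataobj).astype(bool)
    return masks
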