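"""End-to-end orchestration: the joint FLAIR-only analysis and the comparison experiment.

The joint pipeline runs, in order: (1) an initial FLAIR multi-atlas
parcellation, (2) FLAIR-only mixture lesion segmentation guided by that
parcellation, (3) lesion inpainting of the FLAIR image, and (4) a final tissue
segmentation of the corrected image.  Every stage logs its elapsed time and
the SHA-256 of its main output.  In ``flair_only`` mode no T1 input is ever
opened or read.

The comparison experiment runs FLAIR-only and multimodal lesion segmentation
plus T1- and FLAIR-input tissue segmentation over a paired 1.5T/3T phantom
cohort and emits the full set of method-comparison tables and the GM-age GLM
for both volume streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import AtlasDatabase, SegmentTissueConfig, segment_tissue
from .core import (
    ImageVolume,
    LesionMask,
    TissueLabelMap,
    ValidationError,
    VolumeReport,
    read_volume,
)
from .inpaint import INPAINT_MODES, InpaintConfig, inpaint_lesions
from .mixture import MixtureConfig, segment_lesions
from .phantom import Cohort
from .stats import age_association_glm, comparison_table, write_report

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "JointResult",
    "StageError",
    "run_joint_flair",
    "run_joint_flair_from_dir",
    "run_comparison_experiment",
]

MODALITY_MODES = ("flair_only", "t1_reference", "multimodal")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat, JSON-round-trippable pipeline configuration."""

    modality_mode: str = "flair_only"
    inpaint_mode: str = "outlier_filled"
    lesion_threshold: float = 0.5
    min_lesion_diameter_mm: float = 3.0
    max_components_per_class: int = 3
    iterations: int = 1  # parcellate/lesion-segment passes
    atlas_db_path: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality_mode not in MODALITY_MODES:
            raise ValidationError(
                f"modality_mode must be one of {MODALITY_MODES}, got {self.modality_mode!r}"
            )
        if self.inpaint_mode not in INPAINT_MODES:
            raise ValidationError(f"inpaint_mode must be one of {INPAINT_MODES}")
        if not 0 < self.lesion_threshold < 1:
            raise ValidationError("lesion_threshold must be in (0, 1)")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


@dataclass
class JointResult:
    lesions: LesionMask
    tissue: TissueLabelMap
    volumes: VolumeReport
    initial_volumes: VolumeReport
    stage_log: list = field(default_factory=list)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _stage(stage_log: list, name: str, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    elapsed = time.perf_counter() - t0
    stage_log.append({"stage": name, "elapsed_s": round(elapsed, 3)})
    log.info("stage %s done in %.2fs", name, elapsed)
    return out


def run_joint_flair(
    flair: ImageVolume, db: AtlasDatabase, config: Optional[PipelineConfig] = None
) -> JointResult:
    """The joint FLAIR-only analysis: lesions and tissue volumes from one FLAIR.

    Stages: initial parcellation -> lesion segmentation -> inpainting ->
    final tissue segmentation; deterministic under a fixed seed.
    """
    cfg = config or PipelineConfig()
    if "FLAIR" not in db.modality_support:
        raise ValidationError("atlas database does not support FLAIR input")
    stage_log: list = []
    seg_cfg = SegmentTissueConfig()

    initial = _stage(stage_log, "parcellation", segment_tissue, flair, db, config=seg_cfg)
    stage_log[-1]["output_sha"] = _sha(initial.tissue.labels)

    parcellation = initial.tissue
    lesion_result = None
    for _ in range(cfg.iterations):
        lesion_result = _stage(
            stage_log,
            "lesion_segmentation",
            segment_lesions,
            flair,
            None,
            parcellation,
            MixtureConfig(max_components_per_class=cfg.max_components_per_class),
            cfg.lesion_threshold,
            cfg.min_lesion_diameter_mm,
            cfg.seed,
        )
        stage_log[-1]["output_sha"] = _sha(lesion_result.mask.mask)
        stage_log[-1]["lesion_ml"] = lesion_result.volume_ml

    if cfg.inpaint_mode != "uncorrected" and lesion_result.mask.mask.any():
        from .core import WM

        corrected = _stage(
            stage_log,
            "inpainting",
            inpaint_lesions,
            flair,
            lesion_result.mask,
            InpaintConfig(mode=cfg.inpaint_mode),
            wm_mask=parcellation.class_mask(WM),
        )
    else:
        corrected = flair
        stage_log.append({"stage": "inpainting", "elapsed_s": 0.0, "skipped": True})
    stage_log[-1]["output_sha"] = _sha(corrected.data)

    final = _stage(
        stage_log,
        "tissue_segmentation",
        segment_tissue,
        corrected,
        db,
        lesion_result.mask,
        "uncorrected",  # the image is already corrected above
        seg_cfg,
    )
    stage_log[-1]["output_sha"] = _sha(final.tissue.labels)
    return JointResult(
        lesions=lesion_result.mask,
        tissue=final.tissue,
        volumes=final.report,
        initial_volumes=initial.report,
        stage_log=stage_log,
    )


def run_joint_flair_from_dir(
    case_dir, db: AtlasDatabase, config: Optional[PipelineConfig] = None,
    flair_name: str = "flair.nii.gz",
) -> JointResult:
    """Load a case directory and run the joint analysis.

    In ``flair_only`` mode only the FLAIR file is ever opened — a corrupt or
    absent T1 alongside it is irrelevant by construction.
    """
    cfg = config or PipelineConfig()
    case = Path(case_dir)
    flair = read_volume(case / flair_name, expected_modality="FLAIR")
    if cfg.modality_mode != "flair_only":
        raise ValidationError("run_joint_flair_from_dir implements the FLAIR-only mode")
    return run_joint_flair(flair, db, cfg)


# ---------------------------------------------------------------------------
# Comparison experiment


def run_comparison_experiment(
    cohort: Cohort,
    db: AtlasDatabase,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> dict:
    """Method-comparison experiment over a paired-field-strength cohort.

    Per subject and field strength: FLAIR-only and multimodal (FLAIR+T1)
    lesion segmentation against one FLAIR-based parcellation, then T1- and
    FLAIR-input tissue segmentation.  Emits lesion comparison tables per field
    stratum, the tissue no-intercept regressions, and the GM-age GLM for both
    volume streams.  Subjects failing a stage are listed and skipped.
    """
    cfg = config or PipelineConfig()
    seg_cfg = SegmentTissueConfig()
    masks = {"multimodal": {}, "flair_only": {}}
    lesion_vols = {"multimodal": {}, "flair_only": {}}
    tissue_rows = []
    failures = []
    grouping = {}

    for sub in cohort.subjects:
        sid = sub["subject_id"]
        age = sub["age_years"]
        for fieldstr, case in sub["cases"].items():
            key = f"{sid}@{fieldstr}"
            try:
                parc = segment_tissue(case.flair, db, config=seg_cfg).tissue
                mix_cfg = MixtureConfig(max_components_per_class=cfg.max_components_per_class)
                flair_only = segment_lesions(
                    case.flair, None, parc, mix_cfg,
                    cfg.lesion_threshold, cfg.min_lesion_diameter_mm, cfg.seed,
                )
                multimodal = segment_lesions(
                    case.flair, case.t1, parc, mix_cfg,
                    cfg.lesion_threshold, cfg.min_lesion_diameter_mm, cfg.seed,
                )
                tissue = {}
                for modality, image in (("T1", case.t1), ("FLAIR", case.flair)):
                    res = segment_tissue(
                        image, db, lesion_mask=multimodal.mask,
                        inpaint_mode=cfg.inpaint_mode, config=seg_cfg,
                    )
                    tissue[modality] = res.report
            except Exception as exc:  # noqa: BLE001 - collect, continue
                failures.append({"subject": key, "error": str(exc)})
                continue
            grouping[key] = fieldstr
            masks["flair_only"][key] = flair_only.mask
            masks["multimodal"][key] = multimodal.mask
            lesion_vols["flair_only"][key] = flair_only.volume_ml
            lesion_vols["multimodal"][key] = multimodal.volume_ml
            for modality, rep in tissue.items():
                tissue_rows.append(
                    {
                        "subject_id": sid,
                        "field_strength": fieldstr,
                        "age_years": age,
                        "method": modality,
                        "gm_ml": rep.gm_ml,
                        "wm_ml": rep.wm_ml,
                        "csf_ml": rep.csf_ml,
                        "tiv_ml": rep.tiv_ml,
                        "lesion_ml": rep.lesion_ml,
                    }
                )

    tables = comparison_table(
        masks_by_method=masks,
        volumes_by_method=lesion_vols,
        grouping=grouping,
        reference_method="multimodal",
    )
    tissue_frame = pd.DataFrame(tissue_rows)
    report = {"lesions": tables, "tissue_volumes": tissue_frame, "failures": failures}

    if not tissue_frame.empty:
        gm_reg_rows = []
        for fieldstr, grp in tissue_frame.groupby("field_strength"):
            wide = grp.pivot_table(index="subject_id", columns="method", values="gm_ml")
            if {"T1", "FLAIR"} <= set(wide.columns) and len(wide) >= 2:
                from .stats import no_intercept_regression

                reg = no_intercept_regression(wide["T1"].values, wide["FLAIR"].values)
                gm_reg_rows.append(
                    {
                        "field_strength": fieldstr,
                        "beta": reg.beta,
                        "se": reg.se,
                        "r2": reg.r2,
                        "n": reg.n,
                    }
                )
        report["gm_regression"] = pd.DataFrame(gm_reg_rows)
        glms = {}
        for modality, grp in tissue_frame.groupby("method"):
            if len(grp) >= 10:
                fit = age_association_glm(
                    grp["gm_ml"], grp["age_years"], grp["tiv_ml"], grp["field_strength"]
                )
                fit.pop("results")
                glms[modality] = fit
        report["age_glm"] = glms

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(tables, out / "lesions")
        tissue_frame.to_csv(out / "tissue_volumes.csv", index=False)
        extras = {
            "failures": failures,
            "age_glm": report.get("age_glm", {}),
            "gm_regression": report.get("gm_regression", pd.DataFrame()).to_dict("records"),
            "config": dataclasses.asdict(cfg),
        }
        (out / "experiment.json").write_text(json.dumps(extras, indent=2, default=str))
    return report
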