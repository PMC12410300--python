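"""End-to-end workflow: blood-VOI derivation → normalization →
group contrast → organ summaries → method agreement.

The report is a plain (versioned) JSON-serializable dict; every numeric
in it is reproducible by calling the underlying operations directly,
and the t-maps / VOI masks are written as NIfTI next to the report for
external inspection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .agreement import bland_altman, linear_fit
from .blood import (
    BLOOD_DENSITY_G_PER_ML,
    BloodEstimate,
    derive_blood_voi,
    extract_blood_level,
)
from .contrast import run_contrast
from .volio import SubjectScan, Volume, build_analysis_mask, write_nifti

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Thresholds and conventions for one pipeline run.

    Defaults follow the study conventions: blood-VOI derivation at
    p = 0.005 uncorrected, contrast maps at p = 0.05, cluster extent
    > 50 voxels, blood density 1.057 g/mL, 18-connectivity.
    """

    p_blood_voi: float = 0.005
    p_contrast: float = 0.05
    min_cluster: int = 50
    connectivity: int = 18
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML
    slope_refine_frac: float | None = 0.7
    mask_min_value: float = 0.0
    normalizations: tuple[str, ...] = ("blood", "pid")
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_blood_voi, self.p_contrast):
            if not 0.0 < p < 1.0:
                raise ValueError("thresholds must be in (0, 1)")
        if self.min_cluster < 0:
            raise ValueError("min_cluster must be >= 0")


def _split_groups(scans: Sequence[SubjectScan]) -> tuple[list[SubjectScan], list[SubjectScan]]:
    groups: dict[str, list[SubjectScan]] = {}
    for s in scans:
        groups.setdefault(s.group, []).append(s)
    if len(groups) != 2:
        raise ValueError(
            f"contrast workflow needs exactly 2 groups, manifest has {sorted(groups)}"
        )
    (na, ga), (nb, gb) = groups.items()
    return ga, gb


def run_pipeline(
    scans: Sequence[SubjectScan],
    config: RunConfig | None = None,
    organ_masks: Mapping[str, Volume] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full blood-normalization workflow on a two-group cohort.

    Stages: analysis mask → data-driven blood VOI (regression vs ex vivo
    blood) → per-subject image-derived blood levels → image-vs-ex-vivo
    agreement → voxelwise group contrast under each normalization →
    per-organ t summaries.  Requires an ex vivo blood value for every
    subject; without one only the %ID workflow is possible (run
    :func:`petbloodnorm.blood.normalize_to_pid` directly).
    """
    config = config or RunConfig()
    missing = [s.subject_id for s in scans if s.exvivo_blood_Bq_per_g is None]
    if missing:
        raise ValueError(
            f"subjects without ex vivo blood values: {missing}; "
            "the blood-normalization pipeline needs them — use the "
            "normalization-only (%ID) workflow instead"
        )

    stage = "analysis mask"
    try:
        mask = build_analysis_mask(scans, min_value=config.mask_min_value)

        stage = "blood VOI derivation"
        voi_res = derive_blood_voi(
            scans,
            mask,
            p=config.p_blood_voi,
            min_size=config.min_cluster,
            connectivity=config.connectivity,
            density_g_per_mL=config.density_g_per_mL,
            slope_refine_frac=config.slope_refine_frac,
        )

        stage = "blood extraction"
        estimates: dict[str, BloodEstimate] = {
            s.subject_id: extract_blood_level(s, voi_res.voi, config.density_g_per_mL)
            for s in scans
        }

        stage = "agreement"
        exvivo = [float(s.exvivo_blood_Bq_per_g) for s in scans]  # type: ignore[arg-type]
        image = [estimates[s.subject_id].image_blood_Bq_per_g for s in scans]
        fit = linear_fit(exvivo, image)
        ba = bland_altman(exvivo, image)

        stage = "group contrast"
        ga, gb = _split_groups(scans)
        contrasts = {}
        for norm in config.normalizations:
            contrasts[norm] = run_contrast(
                ga,
                gb,
                mask,
                normalization=norm,
                blood=estimates,
                p=config.p_contrast,
                min_size=config.min_cluster,
                connectivity=config.connectivity,
                density_g_per_mL=config.density_g_per_mL,
                organ_masks=organ_masks,
            )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    log.info(
        "pipeline: p_blood_voi=%s p_contrast=%s min_cluster=%s connectivity=%s "
        "density=%s version=%s",
        config.p_blood_voi,
        config.p_contrast,
        config.min_cluster,
        config.connectivity,
        config.density_g_per_mL,
        __version__,
    )

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "config": dataclasses.asdict(config),
        "n_subjects": len(scans),
        "groups": {ga[0].group: len(ga), gb[0].group: len(gb)},
        "blood_voi": dict(voi_res.params),
        "blood_estimates": {
            sid: {
                "image_blood_Bq_per_g": est.image_blood_Bq_per_g,
                "exvivo_blood_Bq_per_g": est.exvivo_blood_Bq_per_g,
            }
            for sid, est in estimates.items()
        },
        "agreement_image_vs_exvivo": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "ci95_slope": list(fit.ci95_slope),
            "bland_altman_bias_Bq_per_g": ba.bias,
            "bland_altman_sd_Bq_per_g": ba.sd_diff,
            "limits_of_agreement_Bq_per_g": [ba.loa_low, ba.loa_high],
        },
        "contrasts": {},
    }
    for norm, res in contrasts.items():
        entry: dict = {
            "contrast": res.tmap.contrast,
            "dof": res.tmap.dof,
            "t_crit": res.params["t_crit"],
            "n_clusters": len(res.clusters),
            "clusters": [
                {
                    "size_voxels": c.size_voxels,
                    "peak_t": c.peak_t,
                    "peak_index": list(c.peak_index),
                }
                for c in res.clusters
            ],
        }
        if res.organ_summary is not None:
            entry["organ_summary"] = {
                name: dataclasses.asdict(s) for name, s in res.organ_summary.items()
            }
        report["contrasts"][norm] = entry

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        spacing = mask.voxel_size_mm
        write_nifti(mask, out_dir / "analysis_mask.nii.gz")
        write_nifti(
            Volume(voi_res.voi.mask().astype(np.int16), spacing, "label"),
            out_dir / "blood_voi.nii.gz",
        )
        write_nifti(voi_res.tmap.t, out_dir / "blood_regression_tmap.nii.gz")
        for norm, res in contrasts.items():
            write_nifti(res.tmap.t, out_dir / f"contrast_tmap_{norm}.nii.gz")
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
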