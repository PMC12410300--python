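"""Voxelwise group contrasts of normalized volumes and organ summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .blood import (
    BLOOD_DENSITY_G_PER_ML,
    BloodEstimate,
    VOI,
    extract_blood_level,
    normalize_to_blood,
    normalize_to_pid,
    voi_mean,
)
from .glm import ClusterVOI, TMap, extract_clusters, t_threshold, two_sample_tmap
from .volio import SubjectScan, Volume

NORMALIZATIONS = ("blood", "pid")


@dataclass
class OrganSummary:
    """Per-organ t-value summary over organ mask ∩ analysis mask."""

    mean_t: float
    peak_t: float
    n_voxels: int
    empty: bool = False


@dataclass
class ContrastResult:
    tmap: TMap
    clusters: list[ClusterVOI]
    normalization: str
    params: dict
    organ_summary: dict[str, OrganSummary] | None = None


@dataclass
class FoldChange:
    """Regional fold change of per-subject mean uptake, A over B."""

    fold: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def _normalize(
    scans: Sequence[SubjectScan],
    normalization: str,
    blood: VOI | Mapping[str, BloodEstimate] | None,
    density_g_per_mL: float,
) -> list[Volume]:
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    if normalization == "pid":
        return [normalize_to_pid(s, density_g_per_mL) for s in scans]
    if blood is None:
        raise ValueError("blood normalization requires a blood VOI or per-subject estimates")
    out = []
    for s in scans:
        if isinstance(blood, VOI):
            est = extract_blood_level(s, blood, density_g_per_mL)
        else:
            try:
                est = blood[s.subject_id]
            except KeyError as e:
                raise ValueError(
                    f"no blood estimate for subject {s.subject_id}"
                ) from e
        out.append(normalize_to_blood(s, est, density_g_per_mL))
    return out


def run_contrast(
    scansA: Sequence[SubjectScan],
    scansB: Sequence[SubjectScan],
    mask: Volume,
    normalization: str,
    blood: VOI | Mapping[str, BloodEstimate] | None = None,
    p: float = 0.05,
    min_size: int = 50,
    connectivity: int = 18,
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML,
    organ_masks: Mapping[str, Volume] | None = None,
) -> ContrastResult:
    """Normalize both groups, compute the A > B pooled t-map, threshold
    one-sided at uncorrected ``p`` (default 0.05, the convention for
    contrast maps; VOI derivation upstream uses 0.005) and keep clusters
    with extent > ``min_size``."""
    idsA = {s.subject_id for s in scansA}
    idsB = {s.subject_id for s in scansB}
    if idsA & idsB:
        raise ValueError(f"groups must be disjoint; shared subjects: {sorted(idsA & idsB)}")
    volsA = _normalize(scansA, normalization, blood, density_g_per_mL)
    volsB = _normalize(scansB, normalization, blood, density_g_per_mL)
    name_a = scansA[0].group
    name_b = scansB[0].group
    tmap = two_sample_tmap(volsA, volsB, mask, contrast=f"{name_a} > {name_b} ({normalization})")
    t_crit = t_threshold(p, tmap.dof, sided="one")
    clusters = extract_clusters(tmap, t_crit, min_size=min_size, connectivity=connectivity)
    summary = organ_t_summary(tmap, organ_masks) if organ_masks is not None else None
    return ContrastResult(
        tmap=tmap,
        clusters=clusters,
        normalization=normalization,
        params={
            "p": p,
            "min_size": min_size,
            "connectivity": connectivity,
            "t_crit": t_crit,
        },
        organ_summary=summary,
    )


def organ_t_summary(
    tmap: TMap, organ_masks: Mapping[str, Volume]
) -> dict[str, OrganSummary]:
    """Mean/peak t and voxel count per organ (mask ∩ analysis mask).

    An organ whose mask misses the analysis mask entirely is reported
    with ``n_voxels=0`` and NaN statistics, flagged ``empty``.
    """
    analysis = tmap.mask.values.astype(bool)
    out: dict[str, OrganSummary] = {}
    for name, mvol in organ_masks.items():
        if mvol.shape != tmap.t.shape:
            raise ValueError(f"organ mask {name!r} grid does not match t-map grid")
        sel = mvol.values.astype(bool) & analysis
        n = int(sel.sum())
        if n == 0:
            out[name] = OrganSummary(mean_t=float("nan"), peak_t=float("nan"), n_voxels=0, empty=True)
        else:
            tv = tmap.t.values[sel]
            out[name] = OrganSummary(
                mean_t=float(tv.mean()), peak_t=float(tv.max()), n_voxels=n
            )
    return out


def regional_fold_change(
    scansA: Sequence[SubjectScan],
    scansB: Sequence[SubjectScan],
    voi: VOI,
    normalization: str,
    blood: VOI | Mapping[str, BloodEstimate] | None = None,
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML,
) -> FoldChange:
    """Fold change of mean VOI uptake (A over B) with an unpaired
    two-tailed t-test on the per-subject means.

    Degenerate zero-variance samples are flagged: identical samples
    give p = 1, separated constant samples give p = 0.
    """
    if len(scansA) < 2 or len(scansB) < 2:
        raise ValueError("each group needs >= 2 subjects")
    volsA = _normalize(scansA, normalization, blood, density_g_per_mL)
    volsB = _normalize(scansB, normalization, blood, density_g_per_mL)
    a = np.array([voi_mean(v, voi) for v in volsA])
    b = np.array([voi_mean(v, voi) for v in volsB])
    if b.mean() == 0:
        raise ValueError("group B mean uptake is zero; fold change undefined")
    fold = float(a.mean() / b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return FoldChange(fold, p, float(a.mean()), float(b.mean()), len(a), len(b), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return FoldChange(
        fold, float(res.pvalue), float(a.mean()), float(b.mean()), len(a), len(b)
    )
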