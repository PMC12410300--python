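"""Blood VOIs, image-derived blood levels, and normalization.

The central operation is the data-driven blood VOI: a voxelwise
regression of every subject's PET volume against the ex vivo blood
radioactivity vector identifies the voxels that track circulating
tracer (the vascular tree); cluster-extent thresholding (p < 0.005
uncorrected, > 50 voxels by default) keeps the stable part of that map.
A pure-blood voxel must regress on the Bq/g blood reference with a
slope close to the blood density (g/mL); by default the VOI is refined
to voxels whose fitted slope reaches a set fraction of that value,
which suppresses partial-blood tissue voxels that would otherwise bias
the image-derived level downward.

Normalization modes:

* blood ratio  — voxelwise Bq/g divided by the subject's image-derived
  blood Bq/g (unitless; 1 over the defining VOI by construction);
* %ID/g        — voxelwise Bq/g divided by injected dose, times 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .glm import TMap, extract_clusters, regression_tmap, t_threshold
from .phantom import BLOOD_DENSITY_G_PER_ML
from .volio import Volume, SubjectScan


class NoClusterError(RuntimeError):
    """No cluster survived thresholding; relax p or min_size."""


@dataclass
class VOI:
    """A volume of interest as an explicit voxel set on a known grid."""

    name: str
    kind: str  # sphere | cylinder | cluster | mask_label
    voxel_indices: np.ndarray  # (n, 3) int
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.intp)
        if len(self.voxel_indices) == 0:
            raise ValueError(f"VOI {self.name!r} rasterized to an empty voxel set")
        if self.voxel_indices.min() < 0 or np.any(
            self.voxel_indices >= np.asarray(self.grid_shape)[None, :]
        ):
            raise ValueError(f"VOI {self.name!r} extends outside the grid")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m


@dataclass
class BloodEstimate:
    """Image-derived blood level for one subject, with its reference."""

    subject_id: str
    image_blood_Bq_per_g: float
    voi_name: str
    exvivo_blood_Bq_per_g: float | None = None

    def __post_init__(self) -> None:
        if self.image_blood_Bq_per_g < 0:
            raise ValueError("image-derived blood level must be >= 0")


@dataclass
class BloodVOIResult:
    """Output of :func:`derive_blood_voi`: the VOI, the regression map,
    and the parameters actually used (recorded for provenance)."""

    voi: VOI
    tmap: TMap
    params: dict


# ---------------------------------------------------------------------------
# Geometric VOIs


def _voxel_centers_mm(grid: Volume) -> tuple[np.ndarray, ...]:
    dx, dy, dz = grid.voxel_size_mm
    nx, ny, nz = grid.shape
    return np.meshgrid(
        np.arange(nx) * dx, np.arange(ny) * dy, np.arange(nz) * dz, indexing="ij"
    )


def sphere_voi(
    center_mm: Sequence[float], radius_mm: float, grid: Volume, name: str = "sphere"
) -> VOI:
    """Sphere VOI: a voxel is included iff its center lies within
    ``radius_mm`` of ``center_mm`` (world/RAS coordinates)."""
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    x, y, z = _voxel_centers_mm(grid)
    cx, cy, cz = (float(c) for c in center_mm)
    inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm**2
    idx = np.argwhere(inside)
    if len(idx) == 0:
        raise ValueError(
            f"sphere at {tuple(center_mm)} mm, r={radius_mm} mm contains no voxel center"
        )
    return VOI(name=name, kind="sphere", voxel_indices=idx, grid_shape=grid.shape)


def cylinder_voi(
    center_mm: Sequence[float],
    radius_mm: float,
    half_length_mm: float,
    grid: Volume,
    axis: int = 2,
    name: str = "cylinder",
) -> VOI:
    """Axis-aligned cylinder VOI (default along the body axis), used for
    the carotid-artery blood region in the cardiac workflow."""
    if radius_mm <= 0 or half_length_mm <= 0:
        raise ValueError("radius and half-length must be > 0")
    coords = _voxel_centers_mm(grid)
    c = [float(v) for v in center_mm]
    lateral = [i for i in range(3) if i != axis]
    r2 = sum((coords[i] - c[i]) ** 2 for i in lateral)
    inside = (r2 <= radius_mm**2) & (np.abs(coords[axis] - c[axis]) <= half_length_mm)
    idx = np.argwhere(inside)
    if len(idx) == 0:
        raise ValueError("cylinder contains no voxel center")
    return VOI(name=name, kind="cylinder", voxel_indices=idx, grid_shape=grid.shape)


def voi_from_mask(mask: np.ndarray, name: str = "mask") -> VOI:
    idx = np.argwhere(np.asarray(mask, dtype=bool))
    return VOI(name=name, kind="mask_label", voxel_indices=idx, grid_shape=mask.shape)


# ---------------------------------------------------------------------------
# Data-driven blood VOI


def derive_blood_voi(
    scans: Sequence[SubjectScan],
    mask: Volume,
    exvivo_blood: Sequence[float] | None = None,
    p: float = 0.005,
    min_size: int = 50,
    connectivity: int = 18,
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML,
    slope_refine_frac: float | None = 0.7,
    seed_point_mm: Sequence[float] | None = None,
) -> BloodVOIResult:
    """Derive the data-driven blood VOI from a cohort.

    Regresses every masked voxel on the ex vivo blood vector, thresholds
    one-sided at ``p`` uncorrected, extracts clusters with extent
    > ``min_size``, and takes the union of survivors (the vascular
    tree).  Options:

    * ``seed_point_mm`` — restrict to the single surviving cluster
      containing that world point (e.g. a heart seed);
    * ``slope_refine_frac`` — keep only voxels whose regression slope is
      at least this fraction of ``density_g_per_mL`` (the slope of a
      whole-blood voxel); ``None`` disables refinement and returns the
      raw cluster union.

    Raises :class:`NoClusterError` when nothing survives, advising to
    relax the thresholds.
    """
    if exvivo_blood is None:
        exvivo_blood = [s.exvivo_blood_Bq_per_g for s in scans]
    if any(b is None for b in exvivo_blood):
        missing = [s.subject_id for s, b in zip(scans, exvivo_blood) if b is None]
        raise ValueError(f"ex vivo blood value required for every scan; missing: {missing}")
    for s in scans:
        s.volume.require_units("Bq/mL")
    blood = np.asarray([float(b) for b in exvivo_blood])

    tmap = regression_tmap(scans, blood, mask, contrast="positive slope vs blood")
    t_crit = t_threshold(p, tmap.dof, sided="one")
    clusters = extract_clusters(tmap, t_crit, min_size=min_size, connectivity=connectivity)
    if not clusters:
        raise NoClusterError(
            f"no cluster survived p={p}, extent>{min_size}; "
            "relax p or min_size, or check the blood vector"
        )
    if seed_point_mm is not None:
        dx, dy, dz = mask.voxel_size_mm
        seed_idx = tuple(
            int(round(c / s)) for c, s in zip(seed_point_mm, (dx, dy, dz))
        )
        containing = [c for c in clusters if c.mask(mask.values.shape)[seed_idx]]
        if not containing:
            raise NoClusterError(
                f"no surviving cluster contains seed point {tuple(seed_point_mm)} mm"
            )
        clusters = containing[:1]

    union = np.zeros(mask.values.shape, dtype=bool)
    for c in clusters:
        union[tuple(c.voxel_indices.T)] = True

    refined_from = int(union.sum())
    if slope_refine_frac is not None:
        assert tmap.slope is not None
        keep = union & (tmap.slope.values >= slope_refine_frac * density_g_per_mL)
        if not keep.any():
            raise NoClusterError(
                "slope refinement removed every voxel; lower slope_refine_frac "
                "or disable refinement"
            )
        union = keep

    voi = VOI(
        name="data_driven_blood",
        kind="cluster",
        voxel_indices=np.argwhere(union),
        grid_shape=mask.values.shape,
    )
    params = {
        "p": p,
        "min_size": min_size,
        "connectivity": connectivity,
        "density_g_per_mL": density_g_per_mL,
        "slope_refine_frac": slope_refine_frac,
        "n_clusters": len(clusters),
        "n_voxels_before_refinement": refined_from,
        "n_voxels": voi.n_voxels,
    }
    return BloodVOIResult(voi=voi, tmap=tmap, params=params)


# ---------------------------------------------------------------------------
# Extraction and normalization


def voi_mean(volume: Volume, voi: VOI) -> float:
    """Arithmetic mean of a volume over a VOI (no unit conversion)."""
    if volume.shape != voi.grid_shape:
        raise ValueError("VOI grid does not match volume grid")
    return float(volume.values[tuple(voi.voxel_indices.T)].mean())


def extract_blood_level(
    scan: SubjectScan,
    voi: VOI,
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML,
) -> BloodEstimate:
    """Image-derived blood level: mean Bq/mL over the VOI, density
    corrected to Bq/g (divide by 1.057 g/mL by default)."""
    scan.volume.require_units("Bq/mL")
    mean_ml = voi_mean(scan.volume, voi)
    return BloodEstimate(
        subject_id=scan.subject_id,
        image_blood_Bq_per_g=mean_ml / density_g_per_mL,
        voi_name=voi.name,
        exvivo_blood_Bq_per_g=scan.exvivo_blood_Bq_per_g,
    )


def normalize_to_blood(
    scan: SubjectScan,
    blood: BloodEstimate,
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML,
) -> Volume:
    """Voxelwise (Bq/mL / density) / image-derived blood Bq/g -> ratio.

    The mean of the result over the defining blood VOI is exactly 1.
    """
    scan.volume.require_units("Bq/mL")
    if not blood.image_blood_Bq_per_g > 0:
        raise ValueError(
            f"subject {scan.subject_id}: blood level must be > 0 to normalize"
        )
    vals = (scan.volume.values / density_g_per_mL) / blood.image_blood_Bq_per_g
    return Volume(vals, scan.volume.voxel_size_mm, "ratio")


def normalize_to_pid(
    scan: SubjectScan,
    density_g_per_mL: float = BLOOD_DENSITY_G_PER_ML,
) -> Volume:
    """Voxelwise (Bq/mL / density) / injected dose x 100 -> %ID/g."""
    scan.volume.require_units("Bq/mL")
    if not scan.injected_dose_Bq > 0:
        raise ValueError(f"subject {scan.subject_id}: missing or invalid injected dose")
    vals = (scan.volume.values / density_g_per_mL) / scan.injected_dose_Bq * 100.0
    return Volume(vals, scan.volume.voxel_size_mm, "%ID/g")
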