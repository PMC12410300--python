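"""Digital-mouse phantom cohorts for late-time-point antibody PET.

The generative model is a linear two-component mixture at a single late
imaging time point, appropriate for a slowly clearing antibody tracer:

    C_i(r) = f_b(r) * B_i  +  s_g * E(r) * ID_i * u            [Bq/g]

where ``f_b(r)`` is the regional blood volume fraction, ``B_i`` the
subject's whole-blood activity concentration, ``s_g`` the group's
specific-binding scale (0 for a knockout that lacks the target
entirely), ``E(r)`` the regional target-expression score and ``ID_i``
the injected dose.  Blood itself clears with inter-subject lognormal
variability:

    B_i = k_blood * ID_i * LN(clearance_cv) * m_g

with ``m_g`` a per-group blood-level multiplier (a knockout that cannot
bind its target retains more tracer in circulation, hence m_KO > 1).
The map is converted to Bq/mL with the blood-density convention
(1.057 g/mL), blurred with a Gaussian point-spread function standing in
for scanner resolution / partial-volume mixing, and degraded with
zero-mean Gaussian noise whose SD grows as sqrt(signal) — a
reconstruction-domain surrogate for Poisson counting noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .volio import Volume, SubjectScan, write_nifti, write_manifest

log = logging.getLogger(__name__)

#: Blood density used to convert between Bq/g and Bq/mL.
BLOOD_DENSITY_G_PER_ML = 1.057

#: Expression-to-uptake coupling (arbitrary units); only ratios matter
#: downstream, so it is fixed.
UPTAKE_COUPLING_U = 1.0

REGION_NAMES = (
    "background",
    "heart_blood_pool",
    "carotid",
    "liver",
    "spleen",
    "lung",
    "bone",
    "bone_marrow",
    "brain_cortex",
    "brain_hippocampus",
    "brain_white_matter",
    "myocardium",
    "infarct",
)

# Per-region blood volume fraction and target-expression score.  Blood
# pool and carotid are whole blood by definition; background is assumed
# signal-free so the body outline defines the analysis mask.
DEFAULT_BLOOD_VOLUME_FRACTION: dict[str, float] = {
    "background": 0.0,
    "heart_blood_pool": 1.0,
    "carotid": 1.0,
    "liver": 0.25,
    "spleen": 0.30,
    "lung": 0.30,
    "bone": 0.05,
    "bone_marrow": 0.15,
    "brain_cortex": 0.04,
    "brain_hippocampus": 0.04,
    "brain_white_matter": 0.03,
    "myocardium": 0.10,
    "infarct": 0.15,
}

# TREM2-like expression: highest in bone marrow (myeloid compartment),
# high in liver, moderate in spleen/lung, low in brain parenchyma and
# healthy myocardium, strongly induced in infarcted tissue.
DEFAULT_TREM2_EXPRESSION: dict[str, float] = {
    "background": 0.0,
    "heart_blood_pool": 0.0,
    "carotid": 0.0,
    "liver": 4.0,
    "spleen": 2.0,
    "lung": 1.5,
    "bone": 0.2,
    "bone_marrow": 5.0,
    "brain_cortex": 1.0,
    "brain_hippocampus": 1.2,
    "brain_white_matter": 0.15,
    "myocardium": 0.3,
    "infarct": 3.0,
}


@dataclass
class PhantomAtlas:
    """Label map plus per-region physiology for the digital mouse."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    labels: Volume  # integer label volume, 0 = background
    label_of: dict[str, int]
    blood_volume_fraction: dict[str, float]
    trem2_expression: dict[str, float]

    def __post_init__(self) -> None:
        if self.blood_volume_fraction["heart_blood_pool"] != 1.0:
            raise ValueError("heart_blood_pool blood volume fraction must be 1")
        if self.blood_volume_fraction["carotid"] != 1.0:
            raise ValueError("carotid blood volume fraction must be 1")
        if self.trem2_expression["background"] != 0.0:
            raise ValueError("background expression must be 0")
        for name, f in self.blood_volume_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"blood volume fraction of {name} outside [0,1]")
        for name, e in self.trem2_expression.items():
            if e < 0:
                raise ValueError(f"expression of {name} negative")

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one region."""
        return self.labels.values == self.label_of[name]

    def region_masks(self, names=None) -> dict[str, Volume]:
        """Binary label Volumes for the requested regions (default: all organs)."""
        if names is None:
            names = [n for n in REGION_NAMES if n != "background"]
        spacing = (self.voxel_size_mm,) * 3
        return {
            n: Volume(self.region_mask(n).astype(np.int16), spacing, "label")
            for n in names
        }

    def per_voxel(self, mapping: Mapping[str, float]) -> np.ndarray:
        """Expand a per-region scalar mapping to a voxel map."""
        out = np.zeros(self.grid_shape, dtype=np.float64)
        for name, lbl in self.label_of.items():
            out[self.labels.values == lbl] = mapping[name]
        return out


@dataclass
class GroupSpec:
    """One cohort arm.

    ``specific_binding_scale`` of 0 encodes a knockout that lacks target
    expression; ``blood_level_multiplier`` > 1 encodes the elevated
    circulating tracer of animals that cannot sequester it in tissue.
    """

    name: str
    specific_binding_scale: float = 0.001
    blood_level_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.specific_binding_scale < 0:
            raise ValueError("specific_binding_scale must be >= 0")
        if not self.blood_level_multiplier > 0:
            raise ValueError("blood_level_multiplier must be > 0")


def default_groups() -> list[GroupSpec]:
    """Wild-type vs target-knockout arms of the whole-body design."""
    return [
        GroupSpec("WT", specific_binding_scale=0.001, blood_level_multiplier=1.0),
        GroupSpec("KO", specific_binding_scale=0.0, blood_level_multiplier=1.3),
    ]


@dataclass
class CohortSpec:
    """Simulation parameters for one cohort.

    Defaults emulate the whole-body wild-type vs knockout study design:
    11 animals per arm, 34 +/- 6 MBq injected, 25% inter-subject
    lognormal blood-clearance variability, 0.8 mm PSF and
    signal-proportional noise at a level giving ~10-20% voxel noise at
    typical late-time activities.
    """

    n_per_group: int = 11
    groups: list[GroupSpec] = field(default_factory=default_groups)
    injected_dose_mean_Bq: float = 3.4e7
    injected_dose_cv: float = 0.18
    clearance_cv: float = 0.25
    psf_sigma_mm: float = 0.8
    noise_scale: float = 100.0
    blood_assay_cv: float = 0.03
    blood_per_dose_per_g: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for v in (
            self.injected_dose_cv,
            self.clearance_cv,
            self.psf_sigma_mm,
            self.noise_scale,
            self.blood_assay_cv,
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError("variability parameters must be finite and >= 0")
        if not np.isfinite(self.injected_dose_mean_Bq) or self.injected_dose_mean_Bq <= 0:
            raise ValueError("injected_dose_mean_Bq must be positive")
        if not np.isfinite(self.blood_per_dose_per_g) or self.blood_per_dose_per_g <= 0:
            raise ValueError("blood_per_dose_per_g must be positive")


@dataclass
class GroundTruth:
    """Latent quantities for one simulated subject."""

    subject_id: str
    group: str
    injected_dose_Bq: float
    true_blood_Bq_per_g: float
    region_specific_uptake_Bq_per_g: dict[str, float]

    def __post_init__(self) -> None:
        vals = [self.injected_dose_Bq, self.true_blood_Bq_per_g, *self.region_specific_uptake_Bq_per_g.values()]
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("ground-truth values must be finite and >= 0")


# ---------------------------------------------------------------------------
# Atlas construction


def _ellipsoid(coords, center, semi):
    cx, cy, cz = center
    ax, ay, az = (max(s, 0.6) for s in semi)
    x, y, z = coords
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _zcylinder(coords, cx, cy, radius, z0, z1):
    x, y, z = coords
    r = max(radius, 0.6)
    return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (z >= z0) & (z <= z1)


def build_default_atlas(
    grid_shape: tuple[int, int, int] = (64, 64, 128),
    voxel_size_mm: float = 0.5,
    blood_volume_fraction: Mapping[str, float] | None = None,
    trem2_expression: Mapping[str, float] | None = None,
) -> PhantomAtlas:
    """Build the 13-region digital-mouse atlas on the given grid.

    The long body axis is the third (z) axis: brain at the head end,
    carotid in the neck, heart (blood pool + myocardium + infarct
    sector) flanked by lungs in the thorax, liver/spleen below, and a
    spine cylinder with a marrow core running along the back.  Regions
    are painted in priority order, so the label map is disjoint by
    construction.  Deterministic given its arguments.
    """
    gx, gy, gz = (int(s) for s in grid_shape)
    if min(gx, gy, gz) < 16:
        raise ValueError(f"grid {grid_shape} too small to place all regions (need >= 16 per axis)")
    coords = np.meshgrid(
        np.arange(gx, dtype=np.float64),
        np.arange(gy, dtype=np.float64),
        np.arange(gz, dtype=np.float64),
        indexing="ij",
    )

    labels = np.zeros((gx, gy, gz), dtype=np.int32)
    label_of = {name: i for i, name in enumerate(REGION_NAMES)}

    def paint(name: str, mask: np.ndarray) -> None:
        labels[mask] = label_of[name]

    # thorax / abdomen geometry in voxel units, scaled off grid extents
    heart_c = (0.5 * gx, 0.40 * gy, 0.58 * gz)
    pool_r = 0.08 * gx
    myo_outer = max(0.13 * gx, pool_r + 1.1)

    # lungs (painted first; heart structures overwrite the medial edges)
    for fx in (0.28, 0.72):
        paint(
            "lung",
            _ellipsoid(coords, (fx * gx, 0.45 * gy, 0.60 * gz), (0.14 * gx, 0.16 * gy, 0.10 * gz)),
        )
    paint("liver", _ellipsoid(coords, (0.5 * gx, 0.55 * gy, 0.40 * gz), (0.30 * gx, 0.22 * gy, 0.08 * gz)))
    paint("spleen", _ellipsoid(coords, (0.78 * gx, 0.62 * gy, 0.38 * gz), (0.08 * gx, 0.08 * gy, 0.05 * gz)))
    marrow_r = max(0.025 * gx, 0.6)
    bone_r = max(0.05 * gx, marrow_r + 1.0)  # cortical shell survives the marrow core
    paint("bone", _zcylinder(coords, 0.5 * gx, 0.78 * gy, bone_r, 0.08 * gz, 0.80 * gz))
    paint("bone_marrow", _zcylinder(coords, 0.5 * gx, 0.78 * gy, marrow_r, 0.08 * gz, 0.80 * gz))

    x, y, z = coords
    r_heart = np.sqrt(
        (x - heart_c[0]) ** 2 + (y - heart_c[1]) ** 2 + (z - heart_c[2]) ** 2
    )
    myo = (r_heart > pool_r) & (r_heart <= myo_outer)
    paint("myocardium", myo)
    # infarct: anterolateral sector of the myocardial shell
    paint("infarct", myo & (x > heart_c[0]) & (z > heart_c[2]))
    paint("heart_blood_pool", r_heart <= pool_r)
    paint("carotid", _zcylinder(coords, 0.42 * gx, 0.40 * gy, 0.03 * gx, 0.68 * gz, 0.80 * gz))

    # brain at the head end, cortex shell / white-matter core / hippocampi
    brain_c = (0.5 * gx, 0.5 * gy, 0.90 * gz)
    brain_semi = (0.30 * gx, 0.30 * gy, 0.065 * gz)
    bx, by, bz = brain_c
    ax_, ay_, az_ = (max(s, 0.6) for s in brain_semi)
    r_brain = np.sqrt(((x - bx) / ax_) ** 2 + ((y - by) / ay_) ** 2 + ((z - bz) / az_) ** 2)
    paint("brain_cortex", r_brain <= 1.0)
    paint("brain_white_matter", r_brain <= 0.62)
    for fx in (0.40, 0.60):
        paint(
            "brain_hippocampus",
            _ellipsoid(coords, (fx * gx, 0.5 * gy, 0.885 * gz), (0.06 * gx, 0.10 * gy, 0.02 * gz)),
        )

    present = set(np.unique(labels))
    missing = [n for n, i in label_of.items() if i not in present]
    if missing:
        raise ValueError(f"grid {grid_shape} too small to place regions: {missing}")

    spacing = (float(voxel_size_mm),) * 3
    return PhantomAtlas(
        grid_shape=(gx, gy, gz),
        voxel_size_mm=float(voxel_size_mm),
        labels=Volume(labels, spacing, "label"),
        label_of=label_of,
        blood_volume_fraction=dict(blood_volume_fraction or DEFAULT_BLOOD_VOLUME_FRACTION),
        trem2_expression=dict(trem2_expression or DEFAULT_TREM2_EXPRESSION),
    )


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(
    atlas: PhantomAtlas, spec: CohortSpec
) -> tuple[list[SubjectScan], list[GroundTruth]]:
    """Simulate one cohort; fully determined by ``(atlas, spec)``.

    Returns scans (volumes in Bq/mL, float64 in memory) and the latent
    per-subject ground truth.  The simulated ex vivo gamma-counter
    measurement is ``B_i * (1 + N(0, blood_assay_cv))``, clipped at zero
    with a warning if the relative error ever exceeds -100%.
    """
    rng = np.random.default_rng(spec.seed)
    fb_map = atlas.per_voxel(atlas.blood_volume_fraction)
    expr_map = atlas.per_voxel(atlas.trem2_expression)
    spacing = (atlas.voxel_size_mm,) * 3
    sigma_vox = spec.psf_sigma_mm / atlas.voxel_size_mm

    def _lognormal_mean1(cv: float, size=None):
        if cv == 0:
            return np.ones(size) if size else 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    scans: list[SubjectScan] = []
    truths: list[GroundTruth] = []
    for group in spec.groups:
        for i in range(spec.n_per_group):
            sid = f"{group.name}_{i + 1:02d}"
            dose = spec.injected_dose_mean_Bq * _lognormal_mean1(spec.injected_dose_cv)
            blood = (
                spec.blood_per_dose_per_g
                * dose
                * _lognormal_mean1(spec.clearance_cv)
                * group.blood_level_multiplier
            )
            uptake = {
                name: group.specific_binding_scale
                * atlas.trem2_expression[name]
                * dose
                * UPTAKE_COUPLING_U
                for name in atlas.label_of
            }
            conc_g = fb_map * blood + group.specific_binding_scale * expr_map * dose * UPTAKE_COUPLING_U
            conc_ml = conc_g * BLOOD_DENSITY_G_PER_ML
            if sigma_vox > 0:
                conc_ml = gaussian_filter(conc_ml, sigma=sigma_vox, mode="constant", cval=0.0)
            if spec.noise_scale > 0:
                sd = spec.noise_scale * np.sqrt(np.maximum(conc_ml, 1e-12))
                conc_ml = conc_ml + rng.standard_normal(conc_ml.shape) * sd
            if spec.blood_assay_cv > 0:
                measured = blood * (1.0 + rng.normal(0.0, spec.blood_assay_cv))
            else:
                measured = blood
            if measured < 0:
                log.warning("subject %s: simulated assay value negative; clipped to 0", sid)
                measured = 0.0
            scans.append(
                SubjectScan(
                    subject_id=sid,
                    group=group.name,
                    injected_dose_Bq=float(dose),
                    volume=Volume(conc_ml, spacing, "Bq/mL"),
                    exvivo_blood_Bq_per_g=float(measured),
                )
            )
            truths.append(
                GroundTruth(
                    subject_id=sid,
                    group=group.name,
                    injected_dose_Bq=float(dose),
                    true_blood_Bq_per_g=float(blood),
                    region_specific_uptake_Bq_per_g=uptake,
                )
            )
    return scans, truths


def write_cohort(
    scans: list[SubjectScan],
    truths: list[GroundTruth],
    atlas: PhantomAtlas,
    out_dir: str | Path,
) -> Path:
    """Write a simulated cohort to disk: NIfTI volumes (float32), CSV
    manifest, atlas label map + JSON label dictionary, ground-truth JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        vpath = out_dir / f"{scan.subject_id}.nii.gz"
        write_nifti(scan.volume, vpath)
        rows.append(
            {
                "subject_id": scan.subject_id,
                "group": scan.group,
                "injected_dose_Bq": scan.injected_dose_Bq,
                "exvivo_blood_Bq_per_g": scan.exvivo_blood_Bq_per_g,
                "volume_path": vpath.name,
            }
        )
    write_manifest(rows, out_dir / "manifest.csv")
    write_nifti(atlas.labels, out_dir / "atlas_labels.nii.gz")
    (out_dir / "atlas_labels.json").write_text(json.dumps(atlas.label_of, indent=2))
    truth_payload = [
        {
            "subject_id": t.subject_id,
            "group": t.group,
            "injected_dose_Bq": t.injected_dose_Bq,
            "true_blood_Bq_per_g": t.true_blood_Bq_per_g,
            "region_specific_uptake_Bq_per_g": t.region_specific_uptake_Bq_per_g,
        }
        for t in truths
    ]
    (out_dir / "ground_truth.json").write_text(json.dumps(truth_payload, indent=2))
    return out_dir / "manifest.csv"
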