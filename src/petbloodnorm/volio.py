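"""Volumes, subject scans and cohort manifests.

All cross-subject statistics in this package assume pre-aligned grids
(the acquisition pipeline coregisters PET to CT); volumes are therefore
required to share shape and voxel spacing, and any mismatch is an error
rather than an implicit resample.

Conventions
-----------
* Voxel indices are 0-based; world coordinates follow the NIfTI RAS+
  affine ``diag(voxel_size_mm)`` so the center of voxel ``(i, j, k)``
  sits at ``(i*dx, j*dy, k*dz)`` mm.
* Every :class:`Volume` carries an explicit physical-units tag which is
  propagated (never silently coerced) by downstream operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Recognised physical-units tags.
UNITS = ("Bq/mL", "Bq/g", "ratio", "%ID/g", "t", "label")

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "injected_dose_Bq",
    "exvivo_blood_Bq_per_g",
    "volume_path",
]


class UnitsError(ValueError):
    """A volume carried the wrong physical units for an operation."""


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class Volume:
    """A 3-D scalar field with voxel spacing (mm) and a units tag."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume must be 3-D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("every volume dimension must be >= 1")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)  # type: ignore[assignment]
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive floats, got {self.voxel_size_mm}")
        if self.units not in UNITS:
            raise UnitsError(f"unknown units {self.units!r}; expected one of {UNITS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine mapping voxel indices to mm."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def require_units(self, units: str) -> None:
        if self.units != units:
            raise UnitsError(f"expected units {units!r}, volume has {self.units!r}")

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Volume":
        return replace(self, values=values, units=units or self.units)


@dataclass
class SubjectScan:
    """One subject's co-registered PET volume plus study metadata."""

    subject_id: str
    group: str
    injected_dose_Bq: float
    volume: Volume
    exvivo_blood_Bq_per_g: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.injected_dose_Bq) or self.injected_dose_Bq <= 0:
            raise ValueError(
                f"subject {self.subject_id}: injected_dose_Bq must be positive"
            )
        if self.exvivo_blood_Bq_per_g is not None:
            v = float(self.exvivo_blood_Bq_per_g)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"subject {self.subject_id}: ex vivo blood must be finite and >= 0"
                )


@dataclass
class CohortManifest:
    """Tabular description of a cohort (one row per subject)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate subject_id values in manifest: {dupes}")


# ---------------------------------------------------------------------------
# NIfTI round trip


def write_nifti(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; scalar data as float32, labels as int16."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if volume.units == "label":
        data = np.asarray(volume.values, dtype=np.int16)
    else:
        data = np.asarray(volume.values, dtype=np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.voxel_size_mm)
    img.header["descrip"] = f"units={volume.units}".encode()[:80]
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path, units: str) -> Volume:
    """Read a NIfTI volume; the caller supplies the physical-units tag."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if units == "label":
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(values=data, voxel_size_mm=zooms, units=units)


# ---------------------------------------------------------------------------
# Cohort loading


def load_cohort(manifest_path: str | Path) -> tuple[list[SubjectScan], CohortManifest]:
    """Load a cohort from a CSV manifest.

    Subjects are returned in manifest order. A missing/blank
    ``exvivo_blood_Bq_per_g`` is allowed (the subject is usable for
    normalization-only workflows); a grid mismatch between any pair of
    volumes is an error naming both subjects.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    manifest = CohortManifest(table=table)
    scans: list[SubjectScan] = []
    for _, row in table.iterrows():
        vpath = Path(row["volume_path"])
        if not vpath.is_absolute():
            vpath = manifest_path.parent / vpath
        if not vpath.exists():
            raise FileNotFoundError(
                f"subject {row['subject_id']}: volume not found at {vpath}"
            )
        vol = read_nifti(vpath, units="Bq/mL")
        exvivo = row["exvivo_blood_Bq_per_g"]
        exvivo = None if pd.isna(exvivo) else float(exvivo)
        scan = SubjectScan(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            injected_dose_Bq=float(row["injected_dose_Bq"]),
            volume=vol,
            exvivo_blood_Bq_per_g=exvivo,
        )
        if scans and not scan.volume.same_grid(scans[0].volume):
            raise GridMismatchError(
                f"subject {scan.subject_id} grid {scan.volume.shape}/"
                f"{scan.volume.voxel_size_mm} does not match subject "
                f"{scans[0].subject_id} grid {scans[0].volume.shape}/"
                f"{scans[0].volume.voxel_size_mm}"
            )
        scans.append(scan)
    return scans, manifest


def write_manifest(rows: pd.DataFrame | list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    CohortManifest(table=table)  # validate
    table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Analysis mask


def build_analysis_mask(
    scans: Sequence[SubjectScan], min_value: float = 0.0
) -> Volume:
    """Binary mask of voxels finite and strictly above ``min_value`` in ALL subjects.

    Mirrors the implicit masking of voxelwise-mapping software: a voxel
    enters the analysis only where every subject has signal.
    """
    if len(scans) < 1:
        raise ValueError("need at least one scan to build an analysis mask")
    first = scans[0].volume
    mask = np.ones(first.shape, dtype=bool)
    for scan in scans:
        if not scan.volume.same_grid(first):
            raise GridMismatchError(
                f"subject {scan.subject_id} is not on the same grid as "
                f"subject {scans[0].subject_id}"
            )
        v = scan.volume.values
        mask &= np.isfinite(v) & (v > min_value)
    if not mask.any():
        raise ValueError(
            "analysis mask is empty: no voxel exceeds "
            f"{min_value} in every subject"
        )
    return Volume(values=mask.astype(np.int16), voxel_size_mm=first.voxel_size_mm, units="label")
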