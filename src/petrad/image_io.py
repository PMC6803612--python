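"""Volume and table I/O plus SUV conversion.

PET volumes are held in standardized-uptake-value (SUV) units, CT volumes in
Hounsfield units (HU).  SUV normalizes the measured activity concentration by
the injected dose per gram of body weight:

    SUV = activity [mCi/mL] / (injected dose [mCi] / body weight [g])

Volumes are written as NIfTI with a diagonal affine built from the voxel
spacing; phantoms are axis-aligned, so no rotation component is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumePair",
    "activity_to_suv",
    "read_volume_pair",
    "write_volume_pair",
    "read_cohort_table",
    "write_cohort_table",
    "read_feature_table",
    "write_feature_table",
    "validate_cohort_table",
]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "smoking",
    "stage",
    "location",
    "egfr_label",
    "injected_dose_mCi",
    "body_weight_g",
]


@dataclass
class VolumePair:
    """Co-registered PET (SUV) and CT (HU) grids for one patient.

    Axis order is (z, y, x); ``spacing`` gives the voxel edge length in mm
    per axis in the same order.
    """

    pet: np.ndarray
    ct: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pet = np.asarray(self.pet, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.pet.ndim != 3 or self.ct.ndim != 3:
            raise ValueError("PET and CT grids must be 3-D")
        if self.pet.shape != self.ct.shape:
            raise ValueError(
                f"PET shape {self.pet.shape} != CT shape {self.ct.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if np.any(self.pet < 0):
            raise ValueError("PET grid contains negative SUV values")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is in mm; 1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0


def activity_to_suv(
    activity: np.ndarray, injected_dose_mci: float, body_weight_g: float
) -> np.ndarray:
    """Convert an activity-concentration grid (mCi/mL) to SUV.

    SUV = activity / (injected_dose / body_weight); dimensionless because the
    conventional assumption of 1 g/mL tissue density makes the units cancel.
    """
    if injected_dose_mci <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mci}")
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    activity = np.asarray(activity, dtype=float)
    if np.any(activity < 0):
        raise ValueError("activity must be non-negative")
    return activity / (injected_dose_mci / body_weight_g)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(grid: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), _affine(tuple(spacing)))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return grid, spacing


def write_volume_pair(pair: VolumePair, out_dir) -> tuple[Path, Path]:
    """Write one PET and one CT NIfTI; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pet_path = out_dir / f"{pair.patient_id}_pet.nii.gz"
    ct_path = out_dir / f"{pair.patient_id}_ct.nii.gz"
    write_volume(pair.pet, pair.spacing, pet_path)
    write_volume(pair.ct, pair.spacing, ct_path)
    return pet_path, ct_path


def read_volume_pair(pet_path, ct_path, meta_row: dict | pd.Series) -> VolumePair:
    """Load a PET/CT pair and attach per-patient metadata.

    Raises on shape or spacing disagreement between the two grids.
    """
    pet, pet_spacing = read_volume(pet_path)
    ct, ct_spacing = read_volume(ct_path)
    if pet.shape != ct.shape:
        raise ValueError(f"PET shape {pet.shape} != CT shape {ct.shape}")
    if not np.allclose(pet_spacing, ct_spacing, rtol=1e-5):
        raise ValueError(f"PET spacing {pet_spacing} != CT spacing {ct_spacing}")
    meta = dict(meta_row)
    return VolumePair(
        pet=pet,
        ct=ct,
        spacing=pet_spacing,
        patient_id=str(meta.get("patient_id", Path(str(pet_path)).stem)),
        meta=meta,
    )


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    if table["patient_id"].duplicated().any():
        raise ValueError("patient_id values must be unique")
    labels = set(table["egfr_label"].unique())
    if not labels <= {"mutant", "wild"}:
        raise ValueError(f"egfr_label must be 'mutant'/'wild', got {sorted(labels)}")
    return table


def write_cohort_table(table: pd.DataFrame, path) -> None:
    validate_cohort_table(table)
    table.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Per-patient feature matrix as CSV, patient_id index preserved."""
    table.to_csv(path, index=True, index_label="patient_id")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
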