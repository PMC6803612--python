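"""Conventional PET quantification on a segmented lesion.

SUVmax, SUVmean and SUVpeak are computed within the VOI; SUVpeak is the mean
SUV inside a 1 cm^3 sphere centred on the hottest voxel (clipped to the grid),
the PERCIST convention.  MTV is the volume of the absolute-threshold metabolic
region in mL, and TLG = MTV x mean SUV of that region; both are zero when the
lesion never exceeds the SUV 2.5 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import TumorROI

__all__ = ["ConventionalMetrics", "compute_conventional_metrics", "METRIC_NAMES"]

METRIC_NAMES = ["suv_max", "suv_mean", "suv_peak", "mtv_ml", "tlg"]

PEAK_SPHERE_VOLUME_ML = 1.0


@dataclass(frozen=True)
class ConventionalMetrics:
    suv_max: float
    suv_mean: float
    suv_peak: float
    mtv_ml: float
    tlg: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _sphere_mask(
    shape: tuple[int, int, int],
    center: tuple[int, int, int],
    spacing: tuple[float, float, float],
    volume_ml: float,
) -> np.ndarray:
    """Voxels whose centres lie within the sphere of the given volume."""
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return d2 <= radius_mm**2


def compute_conventional_metrics(
    pet: np.ndarray,
    roi: TumorROI,
    spacing: tuple[float, float, float],
    peak_volume_ml: float = PEAK_SPHERE_VOLUME_ML,
    tlg_region: str = "mtv",
) -> ConventionalMetrics:
    """SUV statistics plus volumetric metrics for one lesion.

    ``tlg_region`` selects which region's SUVmean multiplies MTV: the
    metabolic region itself (``"mtv"``, default) or the whole VOI (``"voi"``).
    """
    pet = np.asarray(pet, dtype=float)
    if not roi.voi_mask.any():
        raise ValueError("VOI mask is empty")
    if tlg_region not in ("mtv", "voi"):
        raise ValueError(f"tlg_region must be 'mtv' or 'voi', got {tlg_region!r}")

    voi_values = pet[roi.voi_mask]
    suv_max = float(voi_values.max())
    suv_mean = float(voi_values.mean())

    sphere = _sphere_mask(pet.shape, roi.max_index, tuple(spacing), peak_volume_ml)
    suv_peak = float(pet[sphere].mean())

    voxel_ml = float(np.prod(spacing)) / 1000.0
    n_mtv = int(roi.mtv_mask.sum())
    mtv_ml = n_mtv * voxel_ml
    if n_mtv == 0:
        tlg = 0.0
    else:
        region = roi.mtv_mask if tlg_region == "mtv" else roi.voi_mask
        tlg = mtv_ml * float(pet[region].mean())

    return ConventionalMetrics(
        suv_max=suv_max,
        suv_mean=suv_mean,
        suv_peak=suv_peak,
        mtv_ml=mtv_ml,
        tlg=tlg,
    )
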