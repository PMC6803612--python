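"""Tumor delineation on PET by relative-isocontour thresholding.

The volume of interest (VOI) is the set of voxels with SUV at or above 42% of
the lesion SUVmax that are 26-connected to the SUVmax voxel.  Because the seed
point supplied by the caller need not be the hottest voxel, the threshold and
the connected component are iterated to a fixed point: threshold at 42% of the
current maximum, keep the component containing it, update the maximum.

The metabolic tumor volume (MTV) region uses an absolute cutoff instead:
voxels of the lesion's connected component with SUV strictly above 2.5.  A
lesion whose SUVmax does not exceed 2.5 has an empty MTV region by definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["TumorROI", "SegmentationError", "segment_isocontour", "segment_mtv_region"]

RELATIVE_THRESHOLD = 0.42
MTV_CUTOFF_SUV = 2.5

# 26-connectivity in 3-D
_STRUCT3D = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    """Seed point not inside a detectable high-uptake region."""


@dataclass
class TumorROI:
    """Segmented lesion: relative-threshold VOI plus absolute-threshold MTV region."""

    voi_mask: np.ndarray
    mtv_mask: np.ndarray
    analysis_slice_index: int
    threshold_suv: float
    suv_max: float
    max_index: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.voi_mask.any():
            raise SegmentationError("VOI mask is empty")
        if not self.voi_mask[self.max_index]:
            raise SegmentationError("VOI mask does not contain the SUVmax voxel")


def _component_containing(mask: np.ndarray, point: tuple[int, ...]) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=_STRUCT3D)
    lab = labels[point]
    if lab == 0:
        raise SegmentationError(f"point {point} is below the applied threshold")
    return labels == lab


def segment_isocontour(
    pet: np.ndarray,
    seed_point: tuple[int, int, int],
    relative_threshold: float = RELATIVE_THRESHOLD,
    min_seed_suv: float = 1.0,
    mtv_cutoff: float = MTV_CUTOFF_SUV,
) -> TumorROI:
    """Delineate the lesion containing ``seed_point`` at a fraction of SUVmax.

    Parameters
    ----------
    pet
        3-D SUV grid.
    seed_point
        Voxel index inside the lesion's high-uptake region.
    relative_threshold
        Fraction of the lesion SUVmax defining the isocontour (default 0.42).
    min_seed_suv
        Lowest SUV at which a seed is considered to be on a lesion rather
        than in background.
    """
    pet = np.asarray(pet, dtype=float)
    seed_point = tuple(int(i) for i in seed_point)
    if pet[seed_point] < min_seed_suv:
        raise SegmentationError(
            f"seed SUV {pet[seed_point]:.3g} is below the background floor "
            f"{min_seed_suv:.3g}"
        )

    ref_point = seed_point
    current_max = float(pet[seed_point])
    # Fixed-point iteration: the running maximum strictly increases until the
    # hottest voxel of the component is found, so this terminates.
    while True:
        component = _component_containing(pet >= relative_threshold * current_max, ref_point)
        masked = np.where(component, pet, -np.inf)
        new_ref = tuple(int(i) for i in np.unravel_index(int(np.argmax(masked)), pet.shape))
        new_max = float(pet[new_ref])
        ref_point = new_ref
        if new_max <= current_max:
            break
        current_max = new_max

    suv_max = current_max
    threshold_suv = relative_threshold * suv_max
    voi_mask = component

    mtv_mask = _mtv_from_voi(pet, voi_mask, ref_point, mtv_cutoff)

    slice_counts = voi_mask.sum(axis=(1, 2))
    analysis_slice_index = int(np.argmax(slice_counts))

    return TumorROI(
        voi_mask=voi_mask,
        mtv_mask=mtv_mask,
        analysis_slice_index=analysis_slice_index,
        threshold_suv=float(threshold_suv),
        suv_max=float(suv_max),
        max_index=ref_point,
    )


def _mtv_from_voi(
    pet: np.ndarray,
    voi_mask: np.ndarray,
    max_index: tuple[int, int, int],
    cutoff: float,
) -> np.ndarray:
    if pet[max_index] <= cutoff:
        return np.zeros_like(voi_mask, dtype=bool)
    return _component_containing(pet > cutoff, max_index)


def segment_mtv_region(
    pet: np.ndarray, voi: TumorROI, cutoff: float = MTV_CUTOFF_SUV
) -> np.ndarray:
    """Absolute-threshold metabolic region of the lesion ``voi`` delineates.

    Returns the connected component of {SUV > cutoff} containing the lesion's
    hottest voxel, or an all-false mask when SUVmax does not exceed the cutoff.
    """
    pet = np.asarray(pet, dtype=float)
    mask = _mtv_from_voi(pet, voi.voi_mask, voi.max_index, cutoff)
    if not mask.any():
        logger.info(
            "lesion SUVmax %.3g does not exceed the cutoff %.3g; MTV region empty",
            voi.suv_max,
            cutoff,
        )
    return mask
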