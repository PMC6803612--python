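"""Radiomic feature extraction on the segmented tumor slice.

Thirty-eight features per modality, in five families:

* morphology (4): area, perimeter, diameter, concavity — pixel-count
  definitions on the 2-D analysis slice of the lesion mask;
* grayscale statistics, GSS (9): moments of the in-mask intensity
  distribution plus histogram energy/entropy and the gray span (max - min);
* gray-level co-occurrence matrix, GLCM (6): angular second moment, contrast,
  correlation, entropy, homogeneity, dissimilarity, averaged over the four
  principal directions at a one-pixel distance;
* gray level-gradient co-occurrence matrix, GGCM (15): statistics of the
  joint histogram of quantized gray level and Sobel gradient magnitude;
* gray-level difference statistics, GLDS (4): mean, contrast, angular second
  moment and entropy of the absolute-difference histogram, averaged over the
  displacements (0,1), (1,1), (1,0), (1,-1).

Intensities are quantized to 16 equal-width gray levels over the in-mask
range before any co-occurrence counting, and only pixel pairs lying entirely
inside the mask contribute, so features depend on the tumor region alone.
All logarithms are base 2 with the convention 0*log(0) = 0; a co-occurrence
correlation with a zero-variance marginal is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .image_io import VolumePair
from .segmentation import TumorROI

logger = logging.getLogger(__name__)

__all__ = [
    "QuantizedROI",
    "FEATURE_NAMES",
    "GRAY_LEVELS",
    "GLCM_OFFSETS",
    "GLDS_DISPLACEMENTS",
    "quantize",
    "compute_morphology",
    "compute_gss",
    "compute_glcm_features",
    "compute_ggcm_features",
    "compute_glds_features",
    "extract_feature_vector",
]

GRAY_LEVELS = 16
GRADIENT_LEVELS = 16
GLCM_DISTANCE = 1

# (row, col) offsets for angles 0, 45, 90, 135 degrees at distance 1
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
GLCM_ANGLES_DEG: tuple[int, ...] = (0, 45, 90, 135)

# displacements delta = (dx, dy) -> (row, col) offsets (dy, dx)
GLDS_DISPLACEMENTS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))

MORPHOLOGY_NAMES = ["area", "perimeter", "diameter", "concavity"]
GSS_NAMES = [
    "gray_mean",
    "gray_std",
    "skewness",
    "kurtosis",
    "central_moment5",
    "central_moment6",
    "energy",
    "entropy",
    "gray_span",
]
GLCM_NAMES = ["asm", "contrast", "correlation", "entropy", "homogeneity", "dissimilarity"]
GGCM_NAMES = [
    "small_gradient_dominance",
    "big_gradient_dominance",
    "gray_asymmetry",
    "gradient_asymmetry",
    "energy",
    "gray_mean",
    "gradient_mean",
    "gray_variance",
    "gradient_variance",
    "correlation",
    "gray_entropy",
    "gradient_entropy",
    "mixed_entropy",
    "inertia",
    "inverse_difference_moment",
]
GLDS_NAMES = ["mean", "contrast", "asm", "entropy"]

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"morph_{n}" for n in MORPHOLOGY_NAMES]
    + [f"gss_{n}" for n in GSS_NAMES]
    + [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"ggcm_{n}" for n in GGCM_NAMES]
    + [f"glds_{n}" for n in GLDS_NAMES]
)
assert len(FEATURE_NAMES) == 38


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


@dataclass
class QuantizedROI:
    """2-D gray-level image restricted to a mask.

    ``pixels`` holds levels in {0..levels-1}; values outside the mask are
    meaningless and must never enter a statistic.
    """

    pixels: np.ndarray
    mask: np.ndarray
    levels: int


def _quantize_values(values: np.ndarray, vmin: float, vmax: float, levels: int) -> np.ndarray:
    if vmax <= vmin:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def quantize(intensities: np.ndarray, mask: np.ndarray, levels: int = GRAY_LEVELS) -> QuantizedROI:
    """Equal-width binning of the in-mask intensity range into ``levels`` bins.

    A constant region maps to level 0 everywhere.
    """
    intensities = np.asarray(intensities, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = intensities[mask]
    q = _quantize_values(intensities, float(vals.min()), float(vals.max()), levels)
    q[~mask] = 0
    return QuantizedROI(pixels=q, mask=mask, levels=levels)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """In-mask pixels with at least one out-of-mask 4-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def compute_morphology(mask: np.ndarray) -> dict[str, float]:
    """Pixel-count shape descriptors of the 2-D lesion mask.

    * area: number of in-mask pixels;
    * perimeter: number of boundary pixels (4-neighborhood definition);
    * diameter: largest number of pixels on a digital straight line between
      two boundary pixels, i.e. max Chebyshev distance + 1;
    * concavity: (A - B)/B with A the mask area and B its convex-hull area,
      so 0 for convex shapes and negative for indented ones.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    area = float(mask.sum())
    boundary = boundary_pixels(mask)
    perimeter = float(boundary.sum())

    coords = np.argwhere(boundary)
    # Chebyshev diameter: separable per-axis extents do NOT suffice, use pairs.
    if len(coords) == 1:
        diameter = 1.0
    else:
        d = np.abs(coords[:, None, :] - coords[None, :, :]).max(axis=2)
        diameter = float(d.max()) + 1.0

    # hull of pixel centres: a digitized convex set then equals its hull,
    # so concavity is exactly 0 for convex shapes at any resolution
    # degenerate (single-pixel / collinear) masks can rasterize to an
    # undersized hull; the hull can never be smaller than the mask itself
    hull_area = max(
        float(convex_hull_image(mask, offset_coordinates=False).sum()), area
    )
    concavity = (area - hull_area) / hull_area

    return {
        "area": area,
        "perimeter": perimeter,
        "diameter": diameter,
        "concavity": concavity,
    }


# ---------------------------------------------------------------------------
# grayscale statistics
# ---------------------------------------------------------------------------


def compute_gss(
    intensities: np.ndarray, mask: np.ndarray, levels: int = GRAY_LEVELS
) -> dict[str, float]:
    """First-order statistics of the in-mask intensity distribution.

    Moments are population moments of the raw intensities; energy and entropy
    come from the ``levels``-bin normalized histogram; gray span is the
    intensity range.  Skewness and kurtosis of a constant region are 0 by
    convention (kurtosis is non-excess otherwise).
    """
    intensities = np.asarray(intensities, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = intensities[mask]
    mu = float(vals.mean())
    centered = vals - mu
    m2 = float((centered**2).mean())
    std = float(np.sqrt(m2))
    if m2 > 0:
        skewness = float((centered**3).mean()) / m2**1.5
        kurtosis = float((centered**4).mean()) / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0
    m5 = float((centered**5).mean())
    m6 = float((centered**6).mean())

    q = quantize(intensities, mask, levels)
    hist = np.bincount(q.pixels[mask], minlength=levels).astype(float)
    p = hist / hist.sum()
    energy = float((p**2).sum())
    entropy = _entropy_bits(p)
    span = float(vals.max() - vals.min())

    return {
        "gray_mean": mu,
        "gray_std": std,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "central_moment5": m5,
        "central_moment6": m6,
        "energy": energy,
        "entropy": entropy,
        "gray_span": span,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def cooccurrence_matrix(q: QuantizedROI, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one pixel offset.

    Only pairs with both pixels in the mask are counted; returns the
    (levels x levels) matrix summing to 1, or a zero matrix when the offset
    yields no valid pair.
    """
    dr, dc = offset
    pix, mask, g = q.pixels, q.mask, q.levels
    nrow, ncol = mask.shape
    r0 = slice(max(0, -dr), min(nrow, nrow - dr))
    c0 = slice(max(0, -dc), min(ncol, ncol - dc))
    r1 = slice(max(0, dr), min(nrow, nrow + dr))
    c1 = slice(max(0, dc), min(ncol, ncol + dc))
    valid = mask[r0, c0] & mask[r1, c1]
    i = pix[r0, c0][valid]
    j = pix[r1, c1][valid]
    mat = np.zeros((g, g))
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    if total > 0:
        mat /= total
    return mat


def _glcm_scalar_features(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    px = p.sum(axis=1)
    mu_x = float((np.arange(g) * px).sum())
    sig_x = float(np.sqrt(((np.arange(g) - mu_x) ** 2 * px).sum()))
    # symmetric matrix: the two marginals coincide
    if sig_x > 0:
        correlation = float((((i - mu_x) * (j - mu_x) * p).sum()) / (sig_x * sig_x))
    else:
        correlation = 0.0
    entropy = _entropy_bits(p.ravel())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "dissimilarity": dissimilarity,
    }


def compute_glcm_features(
    q: QuantizedROI, offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS
) -> dict[str, float]:
    """Haralick-style features averaged over the four principal directions."""
    per_angle = []
    for off in offsets:
        mat = cooccurrence_matrix(q, off)
        if mat.sum() == 0:
            continue
        per_angle.append(_glcm_scalar_features(mat))
    if not per_angle:
        raise ValueError("no valid in-mask pixel pair for any offset")
    return {name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GGCM
# ---------------------------------------------------------------------------


def sobel_gradient_magnitude(intensities: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the 3x3 Sobel operators."""
    intensities = np.asarray(intensities, dtype=float)
    gr = ndimage.sobel(intensities, axis=0, mode="nearest")
    gc = ndimage.sobel(intensities, axis=1, mode="nearest")
    return np.hypot(gr, gc)


def ggcm_joint_histogram(
    intensities: np.ndarray,
    mask: np.ndarray,
    gray_levels: int = GRAY_LEVELS,
    gradient_levels: int = GRADIENT_LEVELS,
) -> np.ndarray:
    """Normalized joint histogram of quantized gray level and gradient level.

    Statistics are taken over interior pixels — those whose full 3x3 Sobel
    stencil lies inside the mask — so gradients never mix tumor and
    background intensities.  Gray levels bin the interior intensity range;
    gradient levels bin [0, max interior gradient].
    """
    intensities = np.asarray(intensities, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    if not interior.any():
        raise ValueError("mask too small for a 3x3 gradient stencil")
    grad = sobel_gradient_magnitude(intensities)
    vals = intensities[interior]
    gq = _quantize_values(intensities, float(vals.min()), float(vals.max()), gray_levels)
    sq = _quantize_values(grad, 0.0, float(grad[interior].max()), gradient_levels)
    hist = np.zeros((gray_levels, gradient_levels))
    np.add.at(hist, (gq[interior], sq[interior]), 1.0)
    return hist / hist.sum()


def ggcm_features_from_histogram(p: np.ndarray) -> dict[str, float]:
    """The 15 canonical gray-gradient statistics of a normalized joint histogram."""
    g, s = p.shape
    i = np.arange(g)[:, None]
    j = np.arange(s)[None, :]
    p_gray = p.sum(axis=1)
    p_grad = p.sum(axis=0)

    small_grad = float((p / (j + 1.0) ** 2).sum())
    big_grad = float((p * j.astype(float) ** 2).sum())
    gray_asym = float((p_gray**2).sum())
    grad_asym = float((p_grad**2).sum())
    energy = float((p**2).sum())
    mu_i = float((np.arange(g) * p_gray).sum())
    mu_j = float((np.arange(s) * p_grad).sum())
    var_i = float(((np.arange(g) - mu_i) ** 2 * p_gray).sum())
    var_j = float(((np.arange(s) - mu_j) ** 2 * p_grad).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    else:
        correlation = 0.0
    gray_entropy = _entropy_bits(p_gray)
    grad_entropy = _entropy_bits(p_grad)
    mixed_entropy = _entropy_bits(p.ravel())
    inertia = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())

    return {
        "small_gradient_dominance": small_grad,
        "big_gradient_dominance": big_grad,
        "gray_asymmetry": gray_asym,
        "gradient_asymmetry": grad_asym,
        "energy": energy,
        "gray_mean": mu_i,
        "gradient_mean": mu_j,
        "gray_variance": var_i,
        "gradient_variance": var_j,
        "correlation": correlation,
        "gray_entropy": gray_entropy,
        "gradient_entropy": grad_entropy,
        "mixed_entropy": mixed_entropy,
        "inertia": inertia,
        "inverse_difference_moment": idm,
    }


def compute_ggcm_features(
    intensities: np.ndarray,
    mask: np.ndarray,
    gray_levels: int = GRAY_LEVELS,
    gradient_levels: int = GRADIENT_LEVELS,
) -> dict[str, float]:
    p = ggcm_joint_histogram(intensities, mask, gray_levels, gradient_levels)
    return ggcm_features_from_histogram(p)


# ---------------------------------------------------------------------------
# GLDS
# ---------------------------------------------------------------------------


def glds_histogram(q: QuantizedROI, displacement: tuple[int, int]) -> np.ndarray:
    """Normalized histogram of |level differences| for one displacement (dx, dy).

    Pairs must lie entirely inside the mask; returns a zero vector when the
    displacement yields no valid pair.
    """
    dx, dy = displacement
    dr, dc = dy, dx  # (dx, dy) in image (x=col, y=row) convention
    pix, mask, g = q.pixels, q.mask, q.levels
    nrow, ncol = mask.shape
    r0 = slice(max(0, -dr), min(nrow, nrow - dr))
    c0 = slice(max(0, -dc), min(ncol, ncol - dc))
    r1 = slice(max(0, dr), min(nrow, nrow + dr))
    c1 = slice(max(0, dc), min(ncol, ncol + dc))
    valid = mask[r0, c0] & mask[r1, c1]
    diffs = np.abs(pix[r0, c0][valid] - pix[r1, c1][valid])
    hist = np.bincount(diffs, minlength=g).astype(float)[:g]
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist


def _glds_scalar_features(p: np.ndarray) -> dict[str, float]:
    d = np.arange(len(p), dtype=float)
    return {
        "mean": float((d * p).sum()),
        "contrast": float((d**2 * p).sum()),
        "asm": float((p**2).sum()),
        "entropy": _entropy_bits(p),
    }


def compute_glds_features(
    q: QuantizedROI,
    displacements: tuple[tuple[int, int], ...] = GLDS_DISPLACEMENTS,
) -> dict[str, float]:
    """Difference statistics averaged over the four displacements.

    A displacement with no valid in-mask pair is omitted from the average
    with a logged warning.
    """
    per_disp = []
    for disp in displacements:
        hist = glds_histogram(q, disp)
        if hist.sum() == 0:
            logger.warning("displacement %s has no valid in-mask pair; omitted", disp)
            continue
        per_disp.append(_glds_scalar_features(hist))
    if not per_disp:
        raise ValueError("no valid in-mask pixel pair for any displacement")
    return {name: float(np.mean([f[name] for f in per_disp])) for name in GLDS_NAMES}


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------


def _slice_features(intensities: np.ndarray, mask: np.ndarray, gray_levels: int) -> dict[str, float]:
    out: dict[str, float] = {}
    out.update({f"morph_{k}": v for k, v in compute_morphology(mask).items()})
    out.update({f"gss_{k}": v for k, v in compute_gss(intensities, mask, gray_levels).items()})
    q = quantize(intensities, mask, gray_levels)
    out.update({f"glcm_{k}": v for k, v in compute_glcm_features(q).items()})
    out.update(
        {f"ggcm_{k}": v for k, v in compute_ggcm_features(intensities, mask, gray_levels).items()}
    )
    out.update({f"glds_{k}": v for k, v in compute_glds_features(q).items()})
    return {name: out[name] for name in FEATURE_NAMES}


def extract_feature_vector(
    volume: VolumePair,
    roi: TumorROI,
    modality: str,
    slice_mode: str = "largest",
    gray_levels: int = GRAY_LEVELS,
    min_slice_pixels: int = 10,
) -> dict[str, float]:
    """The ordered 38-feature vector for one modality of one lesion.

    ``slice_mode="largest"`` analyses the axial slice with the most in-mask
    pixels; ``"average"`` averages the per-slice vectors over every axial
    slice with at least ``min_slice_pixels`` in-mask pixels.
    """
    if modality not in ("pet", "ct"):
        raise ValueError(f"modality must be 'pet' or 'ct', got {modality!r}")
    grid = volume.pet if modality == "pet" else volume.ct
    if slice_mode == "largest":
        z = roi.analysis_slice_index
        return _slice_features(grid[z], roi.voi_mask[z], gray_levels)
    if slice_mode == "average":
        counts = roi.voi_mask.sum(axis=(1, 2))
        zs = [z for z in range(grid.shape[0]) if counts[z] >= min_slice_pixels]
        if not zs:
            zs = [roi.analysis_slice_index]
        vectors = [_slice_features(grid[z], roi.voi_mask[z], gray_levels) for z in zs]
        return {
            name: float(np.mean([v[name] for v in vectors])) for name in FEATURE_NAMES
        }
    raise ValueError(f"slice_mode must be 'largest' or 'average', got {slice_mode!r}")
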