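"""Brute-force reference implementations used only to check the package.

Every function here recomputes a quantity by direct enumeration over pixels,
pairs or rank assignments, independently of the code paths under test.
"""

from itertools import combinations
from math import comb

import numpy as np


def glcm_pairs(pixels, mask, offset, levels):
    """Exhaustive symmetric pair counting for one co-occurrence offset."""
    mat = np.zeros((levels, levels))
    nrow, ncol = mask.shape
    dr, dc = offset
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c] and mask[r2, c2]:
                mat[pixels[r, c], pixels[r2, c2]] += 1
                mat[pixels[r2, c2], pixels[r, c]] += 1
    if mat.sum() > 0:
        mat /= mat.sum()
    return mat


def glds_hist(pixels, mask, displacement, levels):
    """Exhaustive absolute-difference histogram for one (dx, dy) displacement."""
    dx, dy = displacement
    dr, dc = dy, dx
    nrow, ncol = mask.shape
    hist = np.zeros(levels)
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c] and mask[r2, c2]:
                hist[abs(int(pixels[r, c]) - int(pixels[r2, c2]))] += 1
    if hist.sum() > 0:
        hist /= hist.sum()
    return hist


def joint_gray_gradient_hist(gray_levels_img, grad_levels_img, pixel_set, g, s):
    """Per-pixel tabulation of the joint gray/gradient histogram."""
    hist = np.zeros((g, s))
    for r, c in pixel_set:
        hist[gray_levels_img[r, c], grad_levels_img[r, c]] += 1
    return hist / hist.sum()


def convex_hull_pixel_count(mask):
    """Pixels whose centre lies inside the convex hull of the mask's pixel
    centres (boundary included)."""
    from scipy.spatial import Delaunay

    tri = Delaunay(np.argwhere(mask).astype(float))
    count = 0
    nrow, ncol = mask.shape
    for r in range(nrow):
        for c in range(ncol):
            if tri.find_simplex((r, c)) >= 0:
                count += 1
    return count


def exact_ranksum_p(x, y):
    """Two-sided exact rank-sum p by enumerating all C(n1+n2, n1) assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties expected
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    assert total == comb(len(pooled), n1)
    return count / total


def pairwise_auc(scores, labels):
    """AUC as the fraction of concordant (positive, negative) score pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def sphere_mean(grid, center, spacing, radius_mm):
    """Direct per-voxel sphere averaging."""
    vals = []
    for idx in np.ndindex(grid.shape):
        d2 = sum(((i - c) * s) ** 2 for i, c, s in zip(idx, center, spacing))
        if d2 <= radius_mm**2:
            vals.append(grid[idx])
    return float(np.mean(vals))
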