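# Methods

`petrad` implements a complete PET/CT radiomics workflow for predicting a
binary tumor genotype (EGFR mutant vs wild-type) in non-small-cell lung
cancer: lesion segmentation on PET, conventional PET quantification, a
38-feature radiomic extractor, nonparametric feature screening, and
machine-learned signatures evaluated by repeated cross-validation.  Because
no clinical image archive ships with the package, a synthetic phantom module
generates cohorts with the statistical structure the analysis assumes, so
every stage is testable end to end.

## Segmentation

The volume of interest (VOI) is a relative isocontour: all voxels with
SUV ≥ 0.42 · SUVmax that are 26-connected to the lesion's hottest voxel.
The caller supplies a seed voxel inside the lesion (phantom ground truth or
CLI coordinates); since the seed need not be the hottest voxel, threshold
and component are iterated to a fixed point (the running maximum is
non-decreasing and bounded, so the loop terminates).  The threshold is
inclusive (≥) at the 42% cutoff.  The metabolic region uses a strict
absolute cutoff, SUV > 2.5, on the lesion's connected component; a lesion
whose SUVmax does not exceed 2.5 has MTV = 0 by definition.  VOI masks are
therefore invariant to positive rescaling of the PET grid while metabolic
masks are not — both properties are asserted in tests.  Connectivity is
26-neighborhood in 3-D and 8-neighborhood within slices.

## Conventional PET metrics

SUVmax/SUVmean over the VOI; SUVpeak as the mean SUV in a 1 cm³ sphere
centred on the hottest voxel (the PERCIST convention; the sphere volume is
configurable), clipped to the grid.  MTV is the metabolic-region voxel count
times voxel volume in mL; TLG multiplies MTV by the mean SUV of the
metabolic region.  Averaging over the metabolic region rather than the VOI
is a deliberate choice — TLG is defined from the metabolic volume — and a
`tlg_region="voi"` toggle provides the alternative reading.

## Radiomic features (38 per modality)

Features are computed on the 2-D axial slice with the largest in-mask area
(`slice_mode="largest"`, default) or averaged over all slices with at least
10 in-mask pixels (`slice_mode="average"`); slice-wise analysis follows the
pixel-count morphology definitions below, and the default slice choice is
the package's own convention.

* **Morphology (4).** Area = in-mask pixel count; perimeter = count of
  in-mask pixels with an out-of-mask 4-neighbor; diameter = largest digital
  line between boundary pixels (max pairwise Chebyshev distance + 1);
  concavity = (A − B)/B with B the pixel count of the convex hull.  The hull
  is taken over pixel *centres*, so a digitized convex set equals its hull
  and has concavity exactly 0 at any resolution; corner-offset hulls would
  make even a digital ball appear several percent "concave".  Concavity is
  therefore ≤ 0, more negative for more indented shapes; an absolute-value
  reading is a trivial transform left to the caller.
* **Grayscale statistics (9).** Population moments of in-mask intensities
  (mean, sd, skewness, non-excess kurtosis, raw 5th and 6th central
  moments), energy Σp² and entropy −Σp log₂ p of the 16-bin normalized
  histogram, and gray span (max − min).  A constant region has
  skewness = kurtosis = 0 by convention.
* **Quantization.** Equal-width binning of the in-mask intensity range into
  G = 16 levels; a constant region maps to one level.  Because binning is
  range-relative, all co-occurrence features are invariant under strictly
  increasing affine intensity rescaling.
* **GLCM (6).** Symmetric co-occurrence matrices at distance 1 for offsets
  0°, 45°, 90°, 135°, counting only pixel pairs fully inside the mask,
  normalized to sum 1.  ASM, contrast, correlation, entropy (bits),
  homogeneity 1/(1+(i−j)²)-weighted, and dissimilarity; features are the
  arithmetic mean over the four angles.  Correlation of a zero-variance
  marginal is 0, never NaN.
* **GGCM (15).** Gradient magnitude from 3×3 Sobel operators; statistics
  use interior pixels only (those whose full 3×3 stencil lies in the mask)
  so gradients never mix tumor and background.  Gray levels bin the interior
  intensity range (16 bins); gradient magnitudes bin [0, max] (16 bins).
  From the normalized joint histogram p(i, j): small-/big-gradient
  dominance (Σ p/(j+1)², Σ p·j², with 0-based bins), gray/gradient
  asymmetry (marginal energies), energy, marginal means and variances,
  correlation, three entropies, inertia Σ(i−j)²p, and inverse difference
  moment.  This is the canonical 15-statistic set for gray-gradient
  matrices.
* **GLDS (4).** Absolute level differences at displacements
  (Δx, Δy) = (0,1), (1,1), (1,0), (1,−1) over pairs fully in-mask; mean,
  contrast, ASM and entropy of the normalized difference histogram,
  averaged over the four displacements (a displacement with no valid pair
  is omitted with a warning).

The per-modality vector is fixed-order (4 + 9 + 6 + 15 + 4 = 38); PET and
CT share the mask, hence identical morphology values, and differ only
through intensities.  All histogram code is hand-written because library
co-occurrence routines cannot restrict pair counting to an arbitrary mask;
equivalence with exhaustive brute-force enumeration on small images, and
with `skimage` on full-rectangle masks, is asserted in the test suite.

## Statistics

Wilcoxon rank-sum (exact enumeration for pooled n ≤ 10 without ties,
midrank normal approximation otherwise), Benjamini–Hochberg step-up FDR at
q = 0.10, Spearman correlations between PET radiomic features and
conventional metrics (constant columns yield r = 0, p = 1 with a warning),
and Mann–Whitney AUC with half credit for ties.  Significance against
AUC = 0.5 uses Noether's one-sided z-test with the DeLong
structural-components variance; under label permutation its empirical
type-I error sits at the nominal 5% level (asserted at 2000 permutations).
When the variance estimate degenerates (perfect separation) the null
variance (m+n+1)/(12mn) is substituted as a conservative bound.  Per-feature
screening AUCs are whole-cohort and orientation-free (reported ≥ 0.5);
signature AUCs come from cross-validation only.

## Signatures

LASSO (L1-penalized logistic regression, liblinear path of 12 penalties,
inner stratified 10-fold deviance minimization) selects features; AdaBoost
over depth-1 trees (100 rounds) provides the continuous class score.
Hyperparameters are fixed defaults, configurable in `SignatureSpec`.
Evaluation is stratified 10-fold cross-validation repeated 10 times;
constant-column removal, standardization, selection and fitting all happen
inside each training fold.  Out-of-fold scores are pooled per repeat; the
AUC and the Youden-optimal operating point (sensitivity, specificity,
accuracy as a percent) are averaged across repeats.  If LASSO selects
nothing in some fold, the single feature with the largest training AUC
deviation is used so the fold still produces scores.  A descriptive
whole-cohort selection (`lasso_select` on all rows) is available for
reporting which features drive a signature, but never feeds the performance
numbers.  Clinical covariates enter as 7 columns: age, gender, smoking,
stage (binary III–IV) and lobe location as 3 dummies against an upper-lobe
reference.

Leakage is guarded by construction and by a canary test: a feature column
equal to the labels yields CV AUC ≈ 1, while a feature informative only on
one fold's held-out samples — built from the deterministic split generator
`make_cv_splits` — stays at chance.

## Phantom cohorts

The generator emulates a 115-patient cohort (64 mutant / 51 wild-type).
Lesion support: an ellipsoid (radius drawn from 9–15 mm, ±10% per-axis
anisotropy) radially perturbed by random spherical harmonics of degrees
2–4, normalized to unit RMS and scaled by the class's
boundary-irregularity amplitude (perturbation clipped to [−0.6, 2] to keep
the shape star-shaped, hence connected; amplitude 0 gives a digitized
ellipsoid).  Lesion texture: white noise smoothed by a Gaussian kernel
whose width is the class correlation length, normalized to unit variance
and scaled by the heterogeneity amplitude around the class SUV mean;
background is flat (SUV 0.6) with additive Gaussian noise (sd 0.15).  The
CT channel is generated analogously in HU (lung background −650 HU, noise
20 HU).  Grids are 40×44×44 voxels at 2.5×2×2 mm — coarse enough to keep a
115-patient cohort cheap to simulate, fine enough for ~100-pixel lesion
slices.

Default class parameters place the contrast predominantly in PET (mutant:
hotter, shorter correlation length, larger heterogeneity and irregularity)
while the CT channel carries a weaker, complementary soft-tissue density
contrast.  They were calibrated so the end-to-end cross-validated
discrimination is strong but imperfect (PET/CT AUC ≈ 0.8–0.9), the CT-only
signature clearly weaker (≈ 0.7), and the combined signature at least as
good as either modality alone — the qualitative regime the analysis is
designed for, since no real effect sizes are available to emulate.  Clinical covariates depend on the class only through their
prevalences (smoking 23.4% vs 41.2%, female 57.8% vs 49.0%); age (median
63, range 28–77 via a Beta(2,1) draw), stage (78.3% I–II) and lobe
location are class-independent.  Injected dose (~0.108 mCi/kg) and body
weight are back-filled so the activity→SUV conversion path can be
round-tripped.  PET values are generated directly in SUV.

What the phantoms deliberately omit: scanner point-spread and
partial-volume effects, attenuation/reconstruction artifacts, respiratory
motion, anatomical context, and any radiomics–clinical correlation beyond
the class label.  Passing tests therefore demonstrate that the pipeline
recovers class structure of the kind assumed, not clinical performance on
real images.

## Numerical conventions and problem sizes

Logarithms are base 2 with 0·log 0 = 0; histograms are checked to sum to 1
within 1e−9; ties use midranks throughout; all randomness flows from
explicit integer seeds (patient i of a cohort uses the stream seeded by
(seed, i)), making cohorts and cross-validation results bit-reproducible.
The test suite exercises the full 115-patient default cohort with
10×10-fold evaluation for the class-recovery check and scales other
simulations (null calibration at n = 60 over 20 seeds, 2000 label
permutations for test calibration) to keep a single-CPU run comfortable.

## Known limitations

2-D feature extraction follows the pixel-based feature definitions; no 3-D
texture matrices are offered.  The GGCM feature list is the canonical
15-statistic set; other conventions exist.  Concavity is reported with its
literal (non-positive) sign.  The boosting and LASSO hyperparameters are
sensible fixed defaults rather than tuned values; external validation and
scanner harmonization are out of scope.
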