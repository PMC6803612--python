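import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrad.features import (
    FEATURE_NAMES,
    GLCM_OFFSETS,
    GLDS_DISPLACEMENTS,
    QuantizedROI,
    compute_ggcm_features,
    compute_glcm_features,
    compute_glds_features,
    compute_gss,
    compute_morphology,
    cooccurrence_matrix,
    extract_feature_vector,
    ggcm_joint_histogram,
    glds_histogram,
    quantize,
    sobel_gradient_magnitude,
)
from petrad.image_io import VolumePair
from petrad.segmentation import segment_isocontour

from oracles import convex_hull_pixel_count, glcm_pairs, glds_hist, joint_gray_gradient_hist


def random_roi(seed, size=8, levels=4):
    """Random quantized image with a random connected-ish mask, <= 8x8."""
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, levels, (size, size))
    mask = rng.random((size, size)) < 0.75
    mask[size // 2, size // 2] = True
    return QuantizedROI(pixels=pixels, mask=mask, levels=levels)


class TestMorphology:
    def test_solid_square(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        f = compute_morphology(mask)
        assert f["area"] == 9
        assert f["perimeter"] == 8  # all but the centre pixel
        assert f["diameter"] == 3
        assert f["concavity"] == pytest.approx(0.0)

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        f = compute_morphology(mask)
        assert f["area"] == 1
        assert f["perimeter"] == 1
        assert f["diameter"] == 1

    def test_notched_square_concavity_matches_hull_oracle(self):
        # 4x4 square missing two edge pixels: concave, so (A - B)/B < 0
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:5, 1:5] = True
        mask[1, 2:4] = False
        f = compute_morphology(mask)
        a = mask.sum()
        b = convex_hull_pixel_count(mask)
        assert b > a
        assert f["concavity"] == pytest.approx((a - b) / b)
        assert f["concavity"] < 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_morphology(np.zeros((3, 3), dtype=bool))


class TestQuantize:
    def test_constant_region_single_level(self):
        q = quantize(np.full((4, 4), 3.7), np.ones((4, 4), bool))
        assert (q.pixels == 0).all()

    def test_identity_on_prequantized(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        q = quantize(img, np.ones((4, 4), bool), levels=16)
        np.testing.assert_array_equal(q.pixels, np.arange(16).reshape(4, 4))

    def test_linear_ramp_occupancy_matches_histogram(self):
        img = np.linspace(0, 1, 64).reshape(8, 8)
        mask = np.ones((8, 8), bool)
        q = quantize(img, mask, levels=16)
        counts = np.bincount(q.pixels[mask], minlength=16)
        edges = np.linspace(0, 1, 17)
        edges[-1] += 1e-12
        expected = np.histogram(img[mask], bins=edges)[0]
        np.testing.assert_array_equal(counts, expected)


class TestGSS:
    def test_constant_region_conventions(self):
        f = compute_gss(np.full((4, 4), 2.0), np.ones((4, 4), bool))
        assert f["gray_std"] == 0
        assert f["skewness"] == 0 and f["kurtosis"] == 0
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["gray_span"] == 0

    def test_two_equal_mass_levels(self):
        img = np.array([[0.0, 1.0]] * 4)
        f = compute_gss(img, np.ones((4, 2), bool))
        assert f["entropy"] == pytest.approx(1.0)  # one bit
        assert f["energy"] == pytest.approx(0.5)
        assert f["gray_span"] == pytest.approx(1.0)

    def test_high_moments_match_direct_sums(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, 10)
        img = vals.reshape(2, 5)
        f = compute_gss(img, np.ones((2, 5), bool))
        mu = vals.mean()
        for k, name in [(5, "central_moment5"), (6, "central_moment6")]:
            assert f[name] == pytest.approx(((vals - mu) ** k).mean())
        m2 = ((vals - mu) ** 2).mean()
        assert f["skewness"] == pytest.approx(((vals - mu) ** 3).mean() / m2**1.5)
        assert f["kurtosis"] == pytest.approx(((vals - mu) ** 4).mean() / m2**2)


class TestGLCM:
    def test_worked_example(self):
        # 3x3 image with levels {0,1}: horizontal matrix [[1/6,1/6],[1/6,1/2]]
        img = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])
        q = QuantizedROI(pixels=img, mask=np.ones((3, 3), bool), levels=2)
        mat = cooccurrence_matrix(q, (0, 1))
        np.testing.assert_allclose(
            mat, [[1 / 6, 1 / 6], [1 / 6, 1 / 2]], atol=1e-12
        )
        feats = compute_glcm_features(q, offsets=((0, 1),))
        assert feats["asm"] == pytest.approx(1 / 3)
        assert feats["contrast"] == pytest.approx(1 / 3)

    def test_constant_region(self):
        q = QuantizedROI(pixels=np.zeros((4, 4), int), mask=np.ones((4, 4), bool), levels=16)
        f = compute_glcm_features(q)
        assert f["contrast"] == 0 and f["dissimilarity"] == 0
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["correlation"] == 0.0  # zero-variance convention

    @pytest.mark.parametrize("seed", range(8))
    def test_masked_matrices_match_bruteforce(self, seed):
        q = random_roi(seed)
        for off in GLCM_OFFSETS:
            expected = glcm_pairs(q.pixels, q.mask, off, q.levels)
            np.testing.assert_allclose(
                cooccurrence_matrix(q, off), expected, atol=1e-9
            )

    def test_four_angle_mean_is_arithmetic_mean(self):
        q = random_roi(5)
        mean_feats = compute_glcm_features(q)
        per_angle = [compute_glcm_features(q, offsets=(off,)) for off in GLCM_OFFSETS]
        for name in mean_feats:
            assert mean_feats[name] == pytest.approx(
                np.mean([f[name] for f in per_angle])
            )

    def test_rotation_invariance_after_angle_averaging(self):
        q = random_roi(11)
        rot = QuantizedROI(
            pixels=np.rot90(q.pixels).copy(), mask=np.rot90(q.mask).copy(), levels=q.levels
        )
        f1, f2 = compute_glcm_features(q), compute_glcm_features(rot)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)

    def test_agrees_with_skimage_on_full_mask(self):
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(2)
        img = rng.integers(0, 8, (7, 7)).astype(np.uint8)
        q = QuantizedROI(pixels=img.astype(int), mask=np.ones((7, 7), bool), levels=8)
        mine = cooccurrence_matrix(q, (0, 1))
        ref = graycomatrix(img, [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(mine, ref[:, :, 0, 0], atol=1e-12)
        feats = compute_glcm_features(q, offsets=((0, 1),))
        assert feats["contrast"] == pytest.approx(
            float(graycoprops(ref, "contrast")[0, 0])
        )
        assert feats["correlation"] == pytest.approx(
            float(graycoprops(ref, "correlation")[0, 0]), abs=1e-9
        )


class TestGGCM:
    def test_constant_region(self):
        f = compute_ggcm_features(np.full((5, 5), 4.0), np.ones((5, 5), bool))
        assert f["small_gradient_dominance"] == pytest.approx(1.0)  # maximal
        assert f["inertia"] == pytest.approx(0.0)
        assert f["mixed_entropy"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_histogram_normalization(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 10, (8, 8))
        p = ggcm_joint_histogram(img, np.ones((8, 8), bool))
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ramp_histogram_matches_per_pixel_tabulation(self):
        img = np.add.outer(np.arange(5.0), 2 * np.arange(5.0))
        mask = np.ones((5, 5), bool)
        g, s = 16, 16
        p = ggcm_joint_histogram(img, mask, g, s)

        from scipy import ndimage

        interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
        grad = sobel_gradient_magnitude(img)
        vals = img[interior]
        span = vals.max() - vals.min()
        gq = np.clip(((img - vals.min()) / span * g).astype(int), 0, g - 1)
        gmax = grad[interior].max()
        sq = (
            np.clip((grad / gmax * s).astype(int), 0, s - 1)
            if gmax > 0
            else np.zeros_like(grad, dtype=int)
        )
        expected = joint_gray_gradient_hist(gq, sq, list(map(tuple, np.argwhere(interior))), g, s)
        np.testing.assert_allclose(p, expected, atol=1e-9)

    def test_too_small_mask_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True  # no full 3x3 stencil fits
        with pytest.raises(ValueError, match="stencil"):
            compute_ggcm_features(np.ones((4, 4)), mask)


class TestGLDS:
    def test_constant_region(self):
        q = QuantizedROI(pixels=np.zeros((4, 4), int), mask=np.ones((4, 4), bool), levels=16)
        f = compute_glds_features(q)
        assert f["mean"] == 0 and f["contrast"] == 0
        assert f["asm"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)

    def test_checkerboard_forced_alternation(self):
        pix = np.indices((4, 4)).sum(axis=0) % 2
        q = QuantizedROI(pixels=pix, mask=np.ones((4, 4), bool), levels=2)
        f = compute_glds_features(q, displacements=((0, 1),))
        assert f["mean"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_masked_histograms_match_bruteforce(self, seed):
        q = random_roi(seed, size=6)
        for disp in GLDS_DISPLACEMENTS:
            np.testing.assert_allclose(
                glds_histogram(q, disp),
                glds_hist(q.pixels, q.mask, disp, q.levels),
                atol=1e-9,
            )


class TestAffineInvariance:
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_glcm_glds_invariant_under_increasing_affine(self, scale, shift):
        rng = np.random.default_rng(9)
        img = rng.uniform(0, 10, (8, 8))
        mask = np.ones((8, 8), bool)
        q1 = quantize(img, mask)
        q2 = quantize(scale * img + shift, mask)
        np.testing.assert_array_equal(q1.pixels[mask], q2.pixels[mask])
        f1, f2 = compute_glcm_features(q1), compute_glcm_features(q2)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)
        g1, g2 = compute_glds_features(q1), compute_glds_features(q2)
        for name in g1:
            assert g1[name] == pytest.approx(g2[name], abs=1e-12)


class TestFeatureVector:
    def test_length_and_order(self, uniform_lesion):
        pair, roi, _ = uniform_lesion
        vec = extract_feature_vector(pair, roi, "pet")
        assert list(vec) == list(FEATURE_NAMES)
        assert len(vec) == 38

    def test_morphology_shared_between_modalities(self, tiny_cohort):
        _, cohort = tiny_cohort
        pair, truth = cohort.volumes[0], cohort.truth[0]
        roi = segment_isocontour(pair.pet, truth["seed_point"])
        pet_vec = extract_feature_vector(pair, roi, "pet")
        ct_vec = extract_feature_vector(pair, roi, "ct")
        for name in FEATURE_NAMES:
            if name.startswith("morph_"):
                assert pet_vec[name] == ct_vec[name]
        assert any(
            pet_vec[n] != ct_vec[n] for n in FEATURE_NAMES if not n.startswith("morph_")
        )

    def test_slice_modes_agree_on_z_uniform_lesion(self):
        # cylinder: every axial slice of the lesion is identical
        rng = np.random.default_rng(4)
        profile = rng.uniform(5, 10, (9, 9))
        disk = (np.add.outer((np.arange(9) - 4) ** 2, (np.arange(9) - 4) ** 2)) <= 16
        pet = np.full((7, 11, 11), 0.2)
        for z in range(1, 6):
            pet[z, 1:10, 1:10][disk] = profile[disk]
        ct = np.zeros_like(pet)
        pair = VolumePair(pet=pet, ct=ct, spacing=(2, 2, 2), patient_id="CYL")
        roi = segment_isocontour(pet, (3, 5, 5))
        v1 = extract_feature_vector(pair, roi, "pet", slice_mode="largest")
        v2 = extract_feature_vector(pair, roi, "pet", slice_mode="average")
        for name in FEATURE_NAMES:
            assert v1[name] == pytest.approx(v2[name], rel=1e-9), name

    def test_all_finite_on_phantoms(self, tiny_cohort):
        _, cohort = tiny_cohort
        for pair, truth in zip(cohort.volumes, cohort.truth):
            roi = segment_isocontour(pair.pet, truth["seed_point"])
            for modality in ("pet", "ct"):
                vec = extract_feature_vector(pair, roi, modality)
                assert all(np.isfinite(v) for v in vec.values())
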