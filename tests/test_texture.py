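import numpy as np
import pytest
from scipy.stats import spearmanr

from vastex.image import GrayImage
from vastex.texture import (FEATURE_NAMES, FeatureConfig, cooccurrence_matrix,
                            extract_features, fos_features, frame_features,
                            glds_features, ngtdm, ngtdm_features, sfm_features,
                            sgldm_features)

from . import oracles


def rand_img(rng, h=None, w=None, levels=None):
    h = h or int(rng.integers(6, 11))
    w = w or int(rng.integers(6, 11))
    levels = levels or int(rng.integers(4, 9))
    return GrayImage(rng.integers(0, levels, size=(h, w)), levels=levels)


class TestWorkedExamples:
    def test_fos_two_point_histogram(self):
        img = GrayImage(np.array([[0, 0], [2, 2]]), levels=4)
        agl, sd = fos_features(img)
        assert agl == pytest.approx(1.0)
        assert sd == pytest.approx(1.0)

    def test_cooccurrence_two_row_image(self):
        img = GrayImage(np.array([[0, 0], [1, 1]]), levels=2)
        P = cooccurrence_matrix(img, d=1, theta=0)
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_sgldm_two_row_image_horizontal(self):
        img = GrayImage(np.array([[0, 0], [1, 1]]), levels=2)
        con, cor, ene, hom, ent = sgldm_features(img, d=1, angles=(0,))
        assert con == pytest.approx(0.0)
        assert ene == pytest.approx(0.5)
        assert hom == pytest.approx(1.0)
        assert ent == pytest.approx(np.log10(2))

    def test_glds_uniform_unit_differences(self):
        # columns alternate 0/1 with period 3 mismatch so displacement (3,0)
        # always lands on the opposite level
        col = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        img = GrayImage(np.tile((col[:, None] + col[None, :]) % 2, (1, 1)),
                        levels=2)
        con1, asm, ent1, mean = glds_features(img, displacements=((1, 0),))
        assert con1 == pytest.approx(1.0)
        assert asm == pytest.approx(1.0)
        assert ent1 == pytest.approx(0.0)
        assert mean == pytest.approx(1.0 / 2)

    def test_ngtdm_single_interior_pixel(self):
        arr = np.zeros((5, 5), dtype=int)
        arr[2, 2] = 10
        s, p, ng, n_int = ngtdm(GrayImage(arr, levels=16), d=2)
        assert n_int == 1
        assert ng == 1
        assert s[10] == pytest.approx(10.0)
        assert p[10] == pytest.approx(1.0)
        coa, con2, bus, com, strength, degen = ngtdm_features(s, p, ng, n_int)
        assert degen  # single present level
        assert coa == pytest.approx(1.0 / (1e-8 + 10.0))
        assert con2 == bus == com == strength == 0.0

    def test_sfm_alternating_stripes_anticorrelated(self):
        img = GrayImage(np.tile([0, 1], (8, 4)), levels=2)
        con3, cov, degen = sfm_features(img, lags=((1, 0),))
        assert not degen
        assert cov == pytest.approx(-1.0)
        # sqrt(contrast) = 1; image SD = 0.5, so the normalized value is 2
        assert con3 == pytest.approx(1.0 / img.astype_float().std())


class TestOracleEquivalence:
    def test_full_vector_matches_brute_force(self, rng):
        cfg = FeatureConfig(levels_sgldm=None, levels_glds=None, levels_ngtdm=None)
        for _ in range(10):
            img = rand_img(rng)
            vec, _ = frame_features(img, cfg)
            expect = oracles.full_vector_oracle(img.pixels, img.levels)
            np.testing.assert_allclose(vec, expect, atol=1e-9, rtol=0)

    def test_cooccurrence_matches_skimage(self, rng):
        from skimage.feature import graycomatrix
        img = rand_img(rng, 8, 8, 8)
        # our angles increase counterclockwise with the y axis pointing up;
        # skimage's row axis points down, so 45 and 135 degrees swap
        for theta, angle in ((0, 0.0), (45, 3 * np.pi / 4), (90, np.pi / 2),
                             (135, np.pi / 4)):
            ours = cooccurrence_matrix(img, d=1, theta=theta)
            ref = graycomatrix(img.pixels.astype(np.uint8), [1], [angle],
                               levels=8, symmetric=True, normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestInvariants:
    def test_probability_normalization(self, rng):
        for _ in range(5):
            img = rand_img(rng)
            for theta in (0, 45, 90, 135):
                assert cooccurrence_matrix(img, 1, theta).sum() == pytest.approx(
                    1.0, abs=1e-12)

    def test_transpose_swaps_0_and_90(self, rng):
        img = rand_img(rng, 9, 7, 6)
        imgT = GrayImage(img.pixels.T.copy(), levels=img.levels)
        np.testing.assert_allclose(cooccurrence_matrix(img, 1, 0),
                                   cooccurrence_matrix(imgT, 1, 90), atol=1e-12)
        np.testing.assert_allclose(sgldm_features(img), sgldm_features(imgT),
                                   atol=1e-9)

    def test_feature_ranges_on_random_images(self, rng):
        for _ in range(10):
            img = rand_img(rng)
            vec, _ = frame_features(
                img, FeatureConfig(levels_sgldm=None, levels_glds=None,
                                   levels_ngtdm=None))
            f = dict(zip(FEATURE_NAMES, vec))
            assert 0 <= f["AGL"] <= img.levels - 1
            assert f["SD"] >= 0
            for name in ("ENE", "HOM", "ASM"):
                assert 0 < f[name] <= 1
            for name in ("COR", "COV"):
                assert -1 - 1e-9 <= f[name] <= 1 + 1e-9
            for name in ("CON", "CON1", "CON2", "CON3", "ENT", "ENT1",
                         "COA", "COM", "STR"):
                assert f[name] >= 0
            assert 2 <= f["Df"] <= 3

    def test_entropy_energy_anticorrelated(self, rng):
        ents, enes = [], []
        for _ in range(30):
            img = rand_img(rng, 12, 12)
            _, _, ene, _, ent = sgldm_features(img)
            ents.append(ent)
            enes.append(ene)
        rho, _ = spearmanr(ents, enes)
        assert rho < 0


class TestExtractFeatures:
    def test_single_frame_equals_frame_vector(self, rng):
        img = rand_img(rng, 16, 16, 8)
        vec1, _ = frame_features(img)
        vecN, _ = extract_features([img])
        np.testing.assert_allclose(vec1, vecN)

    def test_identical_frames_average_to_single(self, rng):
        img = rand_img(rng, 16, 16, 8)
        vec1, _ = extract_features([img])
        vec100, _ = extract_features([img] * 20)
        np.testing.assert_allclose(vec1, vec100)

    def test_mean_of_independent_frames(self, rng):
        frames = [rand_img(rng, 16, 16, 8) for _ in range(10)]
        stacked = np.mean([frame_features(f)[0] for f in frames], axis=0)
        vec, _ = extract_features(frames)
        np.testing.assert_allclose(vec, stacked)

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            extract_features([])
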