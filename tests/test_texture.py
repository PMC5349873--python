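import numpy as np
import pytest
from helpers import naive_glcm

from cystrad.texture import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    GLCMMatrix,
    GLCMSpec,
    ImageVolume,
    NoPairsError,
    ROIMask,
    compute_glcm,
    default_specs,
    extract_features,
    first_order_stats,
    glcm_correlation,
    glcm_secondary_stats,
    quantize_roi,
)


def full_mask(shape):
    return ROIMask(np.ones(shape, bool))


class TestQuantize:
    def test_two_point_range(self):
        img = ImageVolume(np.array([0.0, 10.0]).reshape(2, 1, 1))
        q = quantize_roi(img, full_mask((2, 1, 1)), levels=2)
        assert set(q.ravel()) == {0, 1}

    def test_equal_width_binning_by_hand(self):
        img = ImageVolume(np.array([0.0, 1.0, 2.0, 3.0]).reshape(4, 1, 1))
        q = quantize_roi(img, full_mask((4, 1, 1)), levels=2)
        assert q.ravel().tolist() == [0, 0, 1, 1]

    def test_constant_roi_all_zero(self):
        img = ImageVolume(np.full((3, 3, 3), 7.0))
        q = quantize_roi(img, full_mask((3, 3, 3)), levels=32)
        assert (q == 0).all()

    def test_max_maps_to_top_level(self, rng):
        img = ImageVolume(rng.random((5, 5, 5)))
        q = quantize_roi(img, full_mask((5, 5, 5)), levels=8)
        assert q.max() == 7 and q.min() == 0

    def test_outside_mask_is_negative_one(self):
        mask = np.zeros((3, 3, 1), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        img = ImageVolume(np.arange(9.0).reshape(3, 3, 1))
        q = quantize_roi(img, ROIMask(mask), levels=4)
        assert q[2, 2, 0] == -1

    def test_levels_below_two_rejected(self):
        img = ImageVolume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            quantize_roi(img, full_mask((2, 2, 2)), levels=1)


class TestComputeGLCM:
    def test_two_band_pairs_by_hand(self, two_band_image):
        img, mask = two_band_image
        q = quantize_roi(img, mask, 2)
        g = compute_glcm(q, mask, GLCMSpec(direction=(0, 1, 0), levels=2))
        assert g.p[0, 0] == pytest.approx(0.5)
        assert g.p[1, 1] == pytest.approx(0.5)
        assert g.p[0, 1] == 0 and g.p[1, 0] == 0

    def test_checkerboard_pairs(self, checkerboard_image):
        img, mask = checkerboard_image
        q = quantize_roi(img, mask, 2)
        g = compute_glcm(q, mask, GLCMSpec(direction=(0, 1, 0), levels=2))
        assert g.p[0, 1] == pytest.approx(0.5)
        assert g.p[1, 0] == pytest.approx(0.5)

    def test_normalization(self, rng):
        img = ImageVolume(rng.random((6, 6, 6)))
        mask = full_mask((6, 6, 6))
        q = quantize_roi(img, mask, 8)
        for d in ((1, 0, 0), (1, 1, 1), (0, 1, -1)):
            g = compute_glcm(q, mask, GLCMSpec(direction=d, levels=8))
            assert abs(g.p.sum() - 1.0) < 1e-12

    def test_symmetric_invariant_under_offset_negation(self, rng):
        img = ImageVolume(rng.random((6, 6, 6)))
        mask = full_mask((6, 6, 6))
        q = quantize_roi(img, mask, 6)
        a = compute_glcm(q, mask, GLCMSpec(direction=(1, 1, 0), levels=6))
        b_counts = naive_glcm(q, mask.voxels, (-1, -1, 0), 6, symmetric=True)
        assert np.allclose(a.p, b_counts)

    def test_symmetric_matrix_is_symmetric(self, rng):
        img = ImageVolume(rng.random((5, 5, 5)))
        mask = full_mask((5, 5, 5))
        q = quantize_roi(img, mask, 4)
        g = compute_glcm(q, mask, GLCMSpec(direction=(1, 0, 1), levels=4))
        assert np.allclose(g.p, g.p.T)

    def test_matches_naive_oracle_masked(self, rng):
        for _ in range(10):
            img = ImageVolume(rng.random((8, 8, 8)))
            mask = ROIMask(rng.random((8, 8, 8)) < 0.6)
            q = quantize_roi(img, mask, 5)
            d = tuple(rng.choice([-1, 0, 1], size=3))
            if d == (0, 0, 0):
                d = (1, 0, 0)
            g = compute_glcm(q, mask, GLCMSpec(direction=d, levels=5))
            oracle = naive_glcm(q, mask.voxels, d, 5)
            assert np.allclose(g.p, oracle)

    def test_25d_pools_per_slice(self, rng):
        img = ImageVolume(rng.random((6, 6, 4)))
        mask = full_mask((6, 6, 4))
        q = quantize_roi(img, mask, 4)
        spec = GLCMSpec(direction=(1, 0, 0), distance=2, levels=4, mode="2.5D")
        g = compute_glcm(q, mask, spec)
        pooled = sum(
            naive_glcm(q[:, :, k : k + 1], mask.voxels[:, :, k : k + 1], (2, 0, 0), 4)
            * naive_glcm(q[:, :, k : k + 1], mask.voxels[:, :, k : k + 1], (2, 0, 0), 4).sum()
            for k in range(4)
        )
        # recompute unnormalized: naive returns normalized; redo with counts
        counts = np.zeros((4, 4))
        for k in range(4):
            sl = q[:, :, k : k + 1]
            msl = mask.voxels[:, :, k : k + 1]
            c = naive_glcm(sl, msl, (2, 0, 0), 4)
            npairs = (msl[:-2, :, :] & msl[2:, :, :]).sum() * 2  # symmetric doubles
            counts += c * npairs
        assert np.allclose(g.p, counts / counts.sum())

    def test_25d_requires_inplane(self):
        with pytest.raises(ValueError):
            GLCMSpec(direction=(0, 0, 1), mode="2.5D")

    def test_no_pairs_raises(self):
        mask = np.zeros((8, 8, 1), bool)
        mask[0, 0, 0] = mask[4, 4, 0] = True
        img = ImageVolume(np.arange(64.0).reshape(8, 8, 1))
        q = quantize_roi(img, ROIMask(mask), 4)
        with pytest.raises(NoPairsError):
            compute_glcm(q, ROIMask(mask), GLCMSpec(direction=(0, 1, 0), levels=4))

    def test_offset_longer_than_volume(self, rng):
        img = ImageVolume(rng.random((4, 4, 4)))
        mask = full_mask((4, 4, 4))
        q = quantize_roi(img, mask, 4)
        with pytest.raises(NoPairsError):
            compute_glcm(q, mask, GLCMSpec(direction=(1, 0, 0), distance=7, levels=4))


class TestGLCMStatistics:
    def test_two_band_correlation_is_one(self, two_band_image):
        img, mask = two_band_image
        q = quantize_roi(img, mask, 2)
        g = compute_glcm(q, mask, GLCMSpec(direction=(0, 1, 0), levels=2))
        assert glcm_correlation(g) == pytest.approx(1.0)

    def test_checkerboard_correlation_minus_one(self, checkerboard_image):
        img, mask = checkerboard_image
        q = quantize_roi(img, mask, 2)
        g = compute_glcm(q, mask, GLCMSpec(direction=(0, 1, 0), levels=2))
        assert glcm_correlation(g) == pytest.approx(-1.0)

    def test_degenerate_sentinel(self):
        g = GLCMMatrix(p=np.array([[1.0, 0.0], [0.0, 0.0]]), n_pairs=4)
        assert glcm_correlation(g) == 1.0

    def test_correlation_bounds(self, rng):
        mask = full_mask((6, 6, 6))
        for _ in range(25):
            img = ImageVolume(rng.random((6, 6, 6)))
            q = quantize_roi(img, mask, 7)
            g = compute_glcm(q, mask, GLCMSpec(direction=(1, 0, 0), levels=7))
            assert -1.0 <= glcm_correlation(g) <= 1.0

    def test_checkerboard_secondary_stats(self, checkerboard_image):
        img, mask = checkerboard_image
        q = quantize_roi(img, mask, 2)
        g = compute_glcm(q, mask, GLCMSpec(direction=(0, 1, 0), levels=2))
        stats = glcm_secondary_stats(g)
        assert stats["contrast"] == pytest.approx(1.0)
        assert stats["entropy"] == pytest.approx(1.0)

    def test_point_mass_stats(self):
        g = GLCMMatrix(p=np.array([[1.0, 0.0], [0.0, 0.0]]), n_pairs=2)
        stats = glcm_secondary_stats(g)
        assert stats["energy"] == 1.0
        assert stats["entropy"] == 0.0
        assert stats["contrast"] == 0.0

    def test_monotone_affine_intensity_invariance(self, rng):
        base = rng.integers(0, 6, size=(6, 6, 6)).astype(float)
        mask = full_mask((6, 6, 6))
        spec = GLCMSpec(direction=(1, 0, 0), levels=6)
        q1 = quantize_roi(ImageVolume(base), mask, 6)
        q2 = quantize_roi(ImageVolume(3.5 * base + 100.0), mask, 6)
        g1 = compute_glcm(q1, mask, spec)
        g2 = compute_glcm(q2, mask, spec)
        assert np.allclose(g1.p, g2.p)
        assert glcm_correlation(g1) == pytest.approx(glcm_correlation(g2))


class TestFirstOrder:
    def test_population_moments_by_hand(self):
        img = ImageVolume(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        stats = first_order_stats(img, full_mask((4, 1, 1)))
        assert stats["mean"] == pytest.approx(2.5)
        assert stats["sd"] == pytest.approx(np.sqrt(1.25))

    def test_gaussian_kurtosis(self, rng):
        img = ImageVolume(rng.standard_normal((50, 50, 40)))
        stats = first_order_stats(img, full_mask((50, 50, 40)))
        assert stats["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_two_equal_mass_bins_entropy(self):
        img = ImageVolume(np.array([0.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1))
        stats = first_order_stats(img, full_mask((4, 1, 1)), entropy_bins=2)
        assert stats["entropy"] == pytest.approx(1.0)

    def test_zero_variance_kurtosis_missing(self):
        img = ImageVolume(np.full((2, 2, 2), 3.0))
        stats = first_order_stats(img, full_mask((2, 2, 2)))
        assert np.isnan(stats["kurtosis"])


class TestExtractFeatures:
    def test_combinatorial_column_count(self, rng):
        img = ImageVolume(rng.random((8, 8, 8)))
        mask = full_mask((8, 8, 8))
        specs = default_specs(distances=(1, 2), levels=8)
        assert len(specs) == 26
        table = extract_features(
            [(img, mask, "HG"), (img, mask, "LG")],
            specs=specs,
            include_first_order=False,
        )
        assert len(table.columns) == 2 + 26

    def test_identical_volumes_identical_rows(self, rng):
        img = ImageVolume(rng.random((8, 8, 8)))
        mask = full_mask((8, 8, 8))
        table = extract_features(
            [(img, mask, "HG"), (img, mask, "HG")],
            specs=default_specs(distances=(1,), levels=8),
        )
        markers = [c for c in table.columns if c not in ("subject_id", "grade")]
        assert np.allclose(table.loc[0, markers].astype(float), table.loc[1, markers].astype(float))

    def test_missing_feature_dropped_with_warning(self, rng, caplog):
        img = ImageVolume(rng.random((8, 8, 8)))
        sparse = np.zeros((8, 8, 8), bool)
        sparse[0, 0, 0] = sparse[3, 5, 2] = True  # no aligned pair at any offset
        cohort = [(img, full_mask((8, 8, 8)), "HG"), (img, ROIMask(sparse), "LG")]
        specs = default_specs(distances=(1,), levels=4)
        with caplog.at_level("WARNING"):
            table = extract_features(cohort, specs=specs, include_first_order=False)
        assert "dropping" in caplog.text
        assert len(table.columns) == 2  # every GLCM column missing for subject 2

    def test_shape_mismatch_rejected(self, rng):
        img = ImageVolume(rng.random((8, 8, 8)))
        mask = full_mask((8, 8, 9))
        with pytest.raises(ValueError):
            extract_features([(img, mask, "HG")], specs=default_specs(distances=(1,)))

    def test_direction_sets(self):
        assert len(DIRECTIONS_3D) == 13
        assert len(DIRECTIONS_2D) == 4
        seen = set()
        for d in DIRECTIONS_3D:
            assert d != (0, 0, 0)
            assert tuple(-c for c in d) not in seen
            seen.add(d)
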