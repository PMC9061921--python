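"""Texture matrices and features against hand-worked cases and brute-force oracles."""

import numpy as np
import pytest

import oracles
from rectomics.features import (
    adc_first_order,
    aggregate_25d,
    compute_family_features,
    glcm_features,
    glrlm_features,
)
from rectomics.matrices import (
    build_texture_matrix,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_matrix,
)
from conftest import random_roi_slice

CHECKERBOARD = np.tile([[1, 2], [2, 1]], (2, 2)).astype(np.int32)
CONSTANT = np.ones((4, 4), dtype=np.int32)


class TestMatrixConstruction:
    def test_constant_slice_glcm_is_a_point_mass(self):
        m = glcm_matrix(CONSTANT, 1, angle=0)
        p = m.normalized()
        assert p.shape == (1, 1) and p[0, 0] == 1.0

    def test_checkerboard_glcm_has_empty_diagonal(self):
        for angle in (0, 90):
            m = glcm_matrix(CHECKERBOARD, 2, angle=angle)
            assert m.values[0, 0] == 0 and m.values[1, 1] == 0
            assert m.values.sum() == 24  # 12 ordered pairs, symmetrized

    def test_checkerboard_diagonal_pairs_are_equal_levels(self):
        # along 45/135 degrees the same level repeats -> purely diagonal matrix
        m = glcm_matrix(CHECKERBOARD, 2, angle=45)
        assert m.values[0, 1] == 0 and m.values[1, 0] == 0

    def test_checkerboard_glszm_two_diagonal_zones(self):
        # 8-connectivity joins equal-level diagonal neighbours: 2 zones of 8
        m = glszm_matrix(CHECKERBOARD, 2)
        nonzero = {(i, j): int(v) for (i, j), v in np.ndenumerate(m.values) if v}
        assert nonzero == {(0, 7): 1, (1, 7): 1}

    def test_run_length_hand_example(self):
        grid = np.array([[1, 1, 2, 0], [2, 2, 2, 1]], dtype=np.int32)
        m = glrlm_matrix(grid, 2, angle=0)
        # row 1: run (1,len2), run (2,len1); row 2: run (2,len3), run (1,len1)
        assert m.values[0, 1] == 1 and m.values[1, 0] == 1
        assert m.values[1, 2] == 1 and m.values[0, 0] == 1

    def test_background_breaks_runs(self):
        grid = np.array([[1, 0, 1, 1]], dtype=np.int32)
        m = glrlm_matrix(grid, 1, angle=0)
        assert m.values[0, 0] == 1 and m.values[0, 1] == 1

    def test_gldm_dependence_counts_centre_plus_neighbours(self):
        m = gldm_matrix(CONSTANT, 1, alpha=0)
        # corner pixels have 3 equal neighbours -> size 4; centre pixels 8 -> size 9
        assert m.values[0, 3] == 4 and m.values[0, 8] == 4
        assert m.values.sum() == 16

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_texture_matrix("wavelet", CHECKERBOARD)

    @pytest.mark.parametrize("family", ["glcm", "glrlm", "glszm", "gldm"])
    def test_normalized_matrices_sum_to_one(self, family):
        rng = np.random.default_rng(5)
        for _ in range(10):
            grid, ng = random_roi_slice(rng)
            direction = 0 if family in ("glcm", "glrlm") else None
            m = build_texture_matrix(family, grid, direction=direction)
            if m.values.sum() > 0:
                assert m.normalized().sum() == pytest.approx(1.0)

    def test_matrices_match_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            grid, ng = random_roi_slice(rng)
            for angle in (0, 45, 90, 135):
                np.testing.assert_array_equal(
                    glcm_matrix(grid, ng, angle=angle).values, oracles.glcm(grid, ng, angle)
                )
                np.testing.assert_array_equal(
                    glrlm_matrix(grid, ng, angle=angle).values, oracles.glrlm(grid, ng, angle)
                )
            np.testing.assert_array_equal(glszm_matrix(grid, ng).values, oracles.glszm(grid, ng))
            np.testing.assert_allclose(
                ngtdm_matrix(grid, ng).values, oracles.ngtdm(grid, ng), atol=1e-12
            )
            np.testing.assert_array_equal(gldm_matrix(grid, ng).values, oracles.gldm(grid, ng))


class TestFeatureValues:
    def test_constant_slice_closed_forms(self):
        f = glcm_features(glcm_matrix(CONSTANT, 1, angle=0))
        assert f["Contrast"] == 0.0
        assert f["JointEnergy"] == 1.0
        assert f["Correlation"] == 0.0  # zero-variance convention
        rl = glrlm_features(glrlm_matrix(CONSTANT, 1, angle=0))
        # one maximal run per row: 4 runs over 16 pixels
        assert rl["RunPercentage"] == pytest.approx(4 / 16)

    def test_checkerboard_contrast_is_one(self):
        f = glcm_features(glcm_matrix(CHECKERBOARD, 2, angle=0))
        assert f["Contrast"] == pytest.approx(1.0)

    def test_degenerate_matrices_never_nan(self):
        two_px = np.zeros((3, 3), dtype=np.int32)
        two_px[0, 0] = two_px[0, 1] = 2
        for family, direction in [("glcm", 0), ("glrlm", 0), ("glszm", None),
                                  ("ngtdm", None), ("gldm", None)]:
            m = build_texture_matrix(family, two_px, direction=direction)
            values = compute_family_features(family, m)
            assert all(np.isfinite(v) for v in values.values())


class TestAggregation:
    def test_single_slice_identity(self):
        agg = aggregate_25d([{"a": 2.0}])
        assert agg == {"a": 2.0}

    def test_two_slice_mean(self):
        assert aggregate_25d([{"a": 2.0}, {"a": 4.0}])["a"] == 3.0

    def test_directions_averaged_before_slices(self):
        # slice 1: directions (0, 4) -> 2; slice 2: (6,) -> 6; mean = 4
        agg = aggregate_25d([[{"a": 0.0}, {"a": 4.0}], [{"a": 6.0}]])
        assert agg["a"] == 4.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_25d([])

    @pytest.mark.parametrize("transform", [
        lambda g: np.rot90(g).copy(),
        lambda g: np.fliplr(g).copy(),
        lambda g: np.flipud(g).copy(),
    ])
    def test_rotation_and_reflection_invariance(self, transform):
        """Direction-averaged GLCM/GLRLM features are invariant to 90-degree
        rotations and axis flips of every slice."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            grid, ng = random_roi_slice(rng, size_range=(5, 9))
            for fam, builder, feats in [
                ("glcm", glcm_matrix, glcm_features),
                ("glrlm", glrlm_matrix, glrlm_features),
            ]:
                orig = aggregate_25d(
                    [[feats(builder(grid, ng, angle=a)) for a in (0, 45, 90, 135)]]
                )
                rot = aggregate_25d(
                    [[feats(builder(transform(grid), ng, angle=a)) for a in (0, 45, 90, 135)]]
                )
                for k in orig:
                    assert orig[k] == pytest.approx(rot[k], rel=1e-10), (fam, k)


class TestFirstOrder:
    def test_degenerate_constant_sample(self):
        stats = adc_first_order(np.full(10, 1.3))
        assert stats == {"Mean": pytest.approx(1.3), "StandardDeviation": 0.0,
                         "Skewness": 0.0, "Kurtosis": 0.0}

    def test_hand_arithmetic(self):
        stats = adc_first_order(np.array([1.0, 2.0, 3.0, 4.0]))
        assert stats["Mean"] == pytest.approx(2.5)
        assert stats["StandardDeviation"] == pytest.approx(1.29099, abs=1e-5)

    def test_symmetric_sample_has_zero_skewness(self):
        x = np.concatenate([np.linspace(-1, 1, 51)])
        assert adc_first_order(x)["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            adc_first_order(np.array([1.0]))
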