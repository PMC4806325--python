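"""Texture operators against independent brute-force oracles (tol 1e-10)."""

import numpy as np
import pytest

from radiomics_repro.features.texture import (edge_frequency_features,
                                              glcm_features,
                                              glcm_features_from_matrix,
                                              glcm_matrix, gtdm_features,
                                              laws_features,
                                              runlength_features,
                                              spatial_correlation_features)
from radiomics_repro.roi import quantize
from radiomics_repro.volume_io import SegmentationMask, VoxelGrid

import oracles
from conftest import quantized_from_slices

TOL = 1e-10


def _grid_and_mask(img_slices, mask_slices, spacing=(1.0, 1.0, 1.0)):
    img = np.stack([np.asarray(s, dtype=np.float64) for s in img_slices])
    m = np.stack([np.asarray(s, dtype=np.uint8) for s in mask_slices])
    return VoxelGrid(img, spacing), SegmentationMask(m, spacing)


def _random_levels(rng, shape, G):
    """Random level slices with a ragged mask (zeros outside)."""
    L = rng.integers(1, G + 1, size=shape).astype(np.int32)
    hole = rng.random(shape) < 0.2
    L[hole] = 0
    return L


# ---------------------------------------------------------------- GLCM

class TestGLCM:
    def test_constant_roi(self):
        q = quantized_from_slices([np.ones((6, 6), int)], n_levels=4)
        f = glcm_features(q, min_pixels=1)
        assert f["GLCM_Contrast"] == 0.0
        assert f["GLCM_Energy"] == 1.0
        assert f["GLCM_Entropy"] == 0.0

    def test_two_by_two_hand_example(self):
        # [[1,1],[2,2]] with the horizontal offset only: P={(1,1):.5,(2,2):.5}
        from radiomics_repro.roi import QuantizedROI
        levels = np.array([[[1, 1], [2, 2]]], dtype=np.int32)
        G = 2
        C = np.zeros((G, G))
        a, b = levels[0, :, :-1], levels[0, :, 1:]
        for x, y in zip(a.ravel(), b.ravel()):
            C[x - 1, y - 1] += 1
            C[y - 1, x - 1] += 1
        P = C / C.sum()
        f = glcm_features_from_matrix(P)
        assert f["GLCM_Contrast"] == pytest.approx(0.0, abs=TOL)
        assert f["GLCM_Energy"] == pytest.approx(0.5, abs=TOL)
        assert f["GLCM_Entropy"] == pytest.approx(1.0, abs=TOL)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        slices = [_random_levels(rng, (7, 8), 5) for _ in range(2)]
        q = quantized_from_slices(slices, n_levels=5)
        mine = glcm_features(q, min_pixels=1)
        P = oracles.glcm_matrix_bruteforce(slices, 5, min_pixels=1)
        np.testing.assert_allclose(glcm_matrix(q, min_pixels=1), P, atol=TOL)
        ref = oracles.glcm_features_bruteforce(P)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=1e-9), k

    def test_matrix_matches_skimage_on_full_rectangle(self):
        # independent cross-check against scikit-image's GLCM
        from skimage.feature import graycomatrix
        rng = np.random.default_rng(7)
        img = rng.integers(0, 4, size=(8, 8)).astype(np.uint8)
        q = quantized_from_slices([img + 1], n_levels=4)
        mine = glcm_matrix(q, min_pixels=1)
        sk = graycomatrix(img, distances=[1], angles=[0, np.pi / 4, np.pi / 2,
                                                      3 * np.pi / 4],
                          levels=4, symmetric=True, normed=False)
        sk_total = sk[:, :, 0, :].sum(axis=2)
        np.testing.assert_allclose(mine, sk_total / sk_total.sum(), atol=TOL)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        L = _random_levels(rng, (8, 8), 6)
        q1 = quantized_from_slices([L], n_levels=6)
        q2 = quantized_from_slices([np.rot90(L)], n_levels=6)
        f1 = glcm_features(q1, min_pixels=1)
        f2 = glcm_features(q2, min_pixels=1)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=TOL), k


# ---------------------------------------------------------------- GTDM

class TestGTDM:
    def test_constant_roi_guards(self):
        q = quantized_from_slices([np.ones((6, 6), int)], n_levels=4)
        f = gtdm_features(q)
        assert f["GTDM_Coarseness"] == pytest.approx(1e12, rel=1e-6)
        assert f["GTDM_Contrast"] == 0.0

    def test_checkerboard_oracle(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        q = quantized_from_slices([board], n_levels=2)
        mine = gtdm_features(q)
        ref = oracles.gtdm_features_bruteforce([board], 2)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=TOL), k

    @pytest.mark.parametrize("seed", [3, 4])
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        slices = [_random_levels(rng, (8, 8), 4) for _ in range(2)]
        q = quantized_from_slices(slices, n_levels=4)
        mine = gtdm_features(q)
        ref = oracles.gtdm_features_bruteforce(slices, 4)
        if ref is None:
            assert all(np.isnan(v) for v in mine.values())
        else:
            for k, v in ref.items():
                assert mine[k] == pytest.approx(v, abs=1e-9), k

    def test_uniform_hu_offset_invariance(self, rng):
        img = rng.normal(0, 50, size=(1, 8, 8))
        grid1, mask = _grid_and_mask(img, np.ones((1, 8, 8)))
        grid2 = VoxelGrid(img + 500.0, grid1.spacing)
        f1 = gtdm_features(quantize(grid1, mask, 8))
        f2 = gtdm_features(quantize(grid2, mask, 8))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=TOL), k


# ---------------------------------------------------------------- run length

class TestRunLength:
    def test_constant_horizontal_rp(self):
        q = quantized_from_slices([np.ones((4, 4), int)], n_levels=2)
        f = runlength_features(q, directions=("horizontal",))
        assert f["RL_RP"] == pytest.approx(4 / 16, abs=TOL)

    def test_checkerboard_all_unit_runs(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        q = quantized_from_slices([board], n_levels=2)
        f = runlength_features(q, directions=("horizontal", "vertical"))
        assert f["RL_SRE"] == pytest.approx(1.0, abs=TOL)
        assert f["RL_LRE"] == pytest.approx(1.0, abs=TOL)
        assert f["RL_RP"] == pytest.approx(1.0, abs=TOL)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        slices = [_random_levels(rng, (6, 8), 3) for _ in range(2)]
        q = quantized_from_slices(slices, n_levels=3)
        mine = runlength_features(q)
        ref = oracles.runlength_features_bruteforce(
            slices, 3, ("horizontal", "vertical", "diagonal", "antidiagonal"))
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=TOL), k


# ---------------------------------------------------------------- Laws

class TestLaws:
    def test_constant_image_zero_response(self):
        grid, mask = _grid_and_mask([np.full((8, 8), 123.0)], [np.ones((8, 8))])
        f = laws_features(grid, mask)
        for v in f.values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_ramp_annihilation(self):
        ramp = np.tile(np.arange(12.0), (12, 1))
        interior = np.zeros((12, 12))
        interior[3:9, 3:9] = 1  # keep kernels away from the reflected border
        grid, mask = _grid_and_mask([ramp], [interior])
        f = laws_features(grid, mask)
        # E5 responds to the gradient along x (via the L5E5/E5L5 average) ...
        assert f["Laws_L5E5"] > 0
        # ... while the second-difference S5 annihilates a linear ramp
        assert f["Laws_S5S5"] == pytest.approx(0.0, abs=1e-9)

    def test_oracle_equivalence(self, rng):
        img = rng.normal(0, 30, size=(7, 8))
        m = np.ones((7, 8))
        m[0, :2] = 0
        grid, mask = _grid_and_mask([img], [m])
        mine = laws_features(grid, mask)
        ref = oracles.laws_features_bruteforce([img], [m])
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=TOL), k


# ---------------------------------------------------------------- edge frequency

class TestEdgeFrequency:
    def test_constant_roi(self):
        grid, mask = _grid_and_mask([np.full((6, 6), 9.0)], [np.ones((6, 6))])
        f = edge_frequency_features(grid, mask)
        for d in (1, 2, 3):
            assert f[f"EF_d{d}"] == 0.0
        assert f["EF_Coarseness"] == 1.0

    def test_linear_in_contrast(self):
        step = np.zeros((6, 6))
        step[:, 3:] = 10.0
        grid1, mask = _grid_and_mask([step], [np.ones((6, 6))])
        grid2 = VoxelGrid(grid1.data * 2, grid1.spacing)
        f1 = edge_frequency_features(grid1, mask)
        f2 = edge_frequency_features(grid2, mask)
        assert f2["EF_d1"] == pytest.approx(2 * f1["EF_d1"], abs=TOL)

    def test_oracle_equivalence(self, rng):
        img = rng.normal(0, 40, size=(8, 8))
        m = (rng.random((8, 8)) < 0.8).astype(float)
        grid, mask = _grid_and_mask([img], [m])
        mine = edge_frequency_features(grid, mask)
        ref = oracles.edge_frequency_bruteforce([img], [m])
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=TOL), k


# ---------------------------------------------------------------- spatial correlation

class TestSpatialCorrelation:
    def test_flat_roi_convention(self):
        grid, mask = _grid_and_mask([np.full((6, 6), 5.0)], [np.ones((6, 6))])
        f = spatial_correlation_features(grid, mask)
        assert f == {"AutoCorr_X": 1.0, "AutoCorr_Y": 1.0}

    def test_white_noise_near_zero(self, rng):
        img = rng.normal(0, 1, size=(16, 110, 110))
        grid, mask = _grid_and_mask(img, np.ones_like(img))
        f = spatial_correlation_features(grid, mask)
        assert abs(f["AutoCorr_X"]) < 0.05
        assert abs(f["AutoCorr_Y"]) < 0.05

    def test_oracle_equivalence(self, rng):
        img = rng.normal(0, 40, size=(2, 7, 7))
        m = (rng.random((2, 7, 7)) < 0.85).astype(float)
        grid, mask = _grid_and_mask(img, m)
        mine = spatial_correlation_features(grid, mask)
        ref = oracles.spatial_correlation_bruteforce(img, m)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=TOL), k


# ---------------------------------------------------------------- affine invariance of matrix features

def test_matrix_features_affine_invariant(rng):
    img = rng.normal(0, 60, size=(2, 10, 10))
    m = np.ones_like(img)
    grid1, mask = _grid_and_mask(img, m)
    grid2 = VoxelGrid(3.0 * grid1.data + 250.0, grid1.spacing)
    q1 = quantize(grid1, mask, 16)
    q2 = quantize(grid2, mask, 16)
    for fn in (lambda q: glcm_features(q, min_pixels=1), gtdm_features,
               runlength_features):
        f1, f2 = fn(q1), fn(q2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=TOL), k
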