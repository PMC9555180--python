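import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from rangefc import (BrainGrid, build_design_matrix, estimate_smoothness,
                     fit_voxelwise_glm, grf_cluster_correct, label_clusters)
from rangefc.glm import SmoothnessEstimate, TMap


def cube_grid(n, voxel_mm=1.0):
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return BrainGrid(mask=np.ones((n, n, n), bool), affine=affine)


def group_design(n1, n2):
    return np.column_stack([np.ones(n1 + n2), np.r_[np.ones(n1), -np.ones(n2)]])


class TestVoxelwiseGLM:
    def test_reduces_to_pooled_two_sample_t(self, rng):
        n1, n2, V = 12, 9, 40
        Y = rng.standard_normal((n1 + n2, V))
        tmap, _ = fit_voxelwise_glm(Y, group_design(n1, n2))
        expected = stats.ttest_ind(Y[:n1], Y[n1:], equal_var=True).statistic
        np.testing.assert_allclose(tmap.t, expected, rtol=1e-10)
        assert tmap.df == n1 + n2 - 2

    def test_duplicated_group_column_rejected(self, rng):
        X = group_design(5, 5)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            fit_voxelwise_glm(rng.standard_normal((10, 3)), X)

    def test_planted_shift_recovered_at_analytic_scale(self, rng):
        n, V, delta, sigma = 20, 2000, 1.0, 1.0
        Y = rng.standard_normal((2 * n, V)) * sigma
        planted = np.arange(200)
        Y[:n, planted] += delta
        tmap, _ = fit_voxelwise_glm(Y, group_design(n, n))
        expected_t = delta / (sigma * np.sqrt(2.0 / n))
        # per-voxel t is ~unit-variance around expected_t; 200 voxels average
        se_mean = np.sqrt(tmap.df / (tmap.df - 2) / len(planted))
        assert abs(tmap.t[planted].mean() - expected_t) < 3.0 * se_mean + 0.05

    def test_covariate_adjustment_removes_confound_effect(self, rng):
        # signal driven purely by a covariate, groups balanced on it
        n = 30
        cov = rng.standard_normal(2 * n)
        Y = np.outer(cov, np.ones(50)) + 0.1 * rng.standard_normal((2 * n, 50))
        subjects = pd.DataFrame({
            "group": ["patient"] * n + ["control"] * n,
            "age": cov, "sex": ["M", "F"] * n,
        })
        X, names = build_design_matrix(subjects, covariates=("age", "sex"))
        tmap, _ = fit_voxelwise_glm(Y, X)
        assert np.abs(tmap.t).max() < 5.0
        assert names == ["intercept", "group", "age", "sex"]


class TestSmoothnessEstimation:
    def test_white_noise_limit(self, rng):
        # discrete white noise: var(diff)=2 -> FWHM = sqrt(2 ln 2) voxels
        grid = cube_grid(18)
        resid = rng.standard_normal((20, grid.voxel_count))
        est = estimate_smoothness(resid, grid)
        assert np.all(est.fwhm_mm > 1.0) and np.all(est.fwhm_mm < 1.35)

    def test_recovers_smoothing_kernel_within_20_percent(self, rng):
        grid = cube_grid(24, voxel_mm=3.0)  # kernel FWHM 12 mm = 4 voxels
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        vols = ndimage.gaussian_filter(
            rng.standard_normal((12, 24, 24, 24)), sigma=(0, sigma, sigma, sigma))
        est = estimate_smoothness(vols.reshape(12, -1), grid)
        assert np.all(est.fwhm_mm > 0.8 * 12.0) and np.all(est.fwhm_mm < 1.2 * 12.0)
        assert est.resel_count == pytest.approx(
            grid.voxel_count * 27.0 / np.prod(est.fwhm_mm))

    def test_fwhm_scales_with_voxel_size(self, rng):
        resid = rng.standard_normal((15, 10 ** 3))
        est1 = estimate_smoothness(resid, cube_grid(10, voxel_mm=2.0))
        est2 = estimate_smoothness(resid, cube_grid(10, voxel_mm=4.0))
        np.testing.assert_allclose(est2.fwhm_mm, 2.0 * est1.fwhm_mm, rtol=1e-12)

    def test_constant_residuals_rejected(self):
        grid = cube_grid(6)
        with pytest.raises(ValueError):
            estimate_smoothness(np.ones((12, grid.voxel_count)), grid)

    def test_too_few_maps_rejected(self, rng):
        grid = cube_grid(6)
        with pytest.raises(ValueError, match="at least 10"):
            estimate_smoothness(rng.standard_normal((5, grid.voxel_count)), grid)


class TestClusterCorrection:
    def smoothness(self, grid, fwhm_vox=3.0):
        fwhm = np.full(3, fwhm_vox)
        return SmoothnessEstimate(
            fwhm_mm=fwhm, resel_count=grid.voxel_count / fwhm_vox ** 3,
            search_volume_voxels=grid.voxel_count)

    def test_zero_t_map_gives_empty_table(self):
        grid = cube_grid(12)
        table = grf_cluster_correct(TMap(t=np.zeros(grid.voxel_count), df=40),
                                    self.smoothness(grid), grid)
        assert len(table) == 0

    def test_planted_blob_detected_with_matching_sign(self, rng):
        grid = cube_grid(16)
        t = 0.2 * rng.standard_normal(grid.voxel_count)
        vol = grid.vector_to_volume(t)
        vol[4:9, 4:9, 4:9] = -8.0
        t = grid.volume_to_vector(vol)
        table = grf_cluster_correct(TMap(t=t, df=40), self.smoothness(grid), grid)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["tail"] == -1 and row["peak_t"] == pytest.approx(-8.0)
        assert row["n_voxels"] == 125
        assert 0.0 < row["corrected_p"] <= 1.0

    def test_raising_voxel_threshold_shrinks_clusters(self, rng):
        grid = cube_grid(16)
        vol = ndimage.gaussian_filter(np.random.default_rng(1).standard_normal((16,) * 3), 1.3)
        vol[5:10, 5:10, 5:10] += 3.0
        t = grid.volume_to_vector(vol / vol.std() * 3.0)
        smooth = self.smoothness(grid)
        loose = grf_cluster_correct(TMap(t=t, df=60), smooth, grid,
                                    voxel_p=0.01, cluster_p=1.0)
        strict = grf_cluster_correct(TMap(t=t, df=60), smooth, grid,
                                     voxel_p=0.001, cluster_p=1.0)
        assert strict["n_voxels"].sum() <= loose["n_voxels"].sum()

    def test_corrected_p_decreases_with_cluster_size(self):
        # same smoothness, bigger planted blob -> smaller corrected p
        grid = cube_grid(20)
        ps = []
        for w in (3, 5, 7):
            vol = np.zeros((20,) * 3)
            vol[2:2 + w, 2:2 + w, 2:2 + w] = 8.0
            table = grf_cluster_correct(TMap(t=grid.volume_to_vector(vol), df=40),
                                        self.smoothness(grid), grid, cluster_p=1.0)
            ps.append(table.iloc[0]["corrected_p"])
        assert ps[0] > ps[1] > ps[2]

    def test_zero_resels_rejected(self):
        grid = cube_grid(8)
        bad = SmoothnessEstimate(fwhm_mm=np.ones(3), resel_count=0.0,
                                 search_volume_voxels=grid.voxel_count)
        with pytest.raises(ValueError):
            grf_cluster_correct(TMap(t=np.zeros(grid.voxel_count), df=10), bad, grid)


class TestLabelClusters:
    def table_for(self, grid):
        vol = np.zeros(grid.mask.shape)
        vol[2:6, 2:6, 2:6] = 9.0
        return grf_cluster_correct(TMap(t=grid.volume_to_vector(vol), df=40),
                                   SmoothnessEstimate(np.full(3, 3.0),
                                                      grid.voxel_count / 27.0,
                                                      grid.voxel_count),
                                   grid, cluster_p=1.0)

    def test_without_atlas_labels_are_coordinates(self):
        grid = cube_grid(12)
        table = self.table_for(grid)
        assert table.iloc[0]["label"].startswith("(")

    def test_single_region_atlas_labels_everything(self):
        import nibabel as nib
        grid = cube_grid(12)
        table = self.table_for(grid)
        atlas = nib.Nifti1Image(np.ones(grid.mask.shape, dtype=np.int16), grid.affine)
        labelled = label_clusters(table, grid, atlas, atlas_names={1: "regionA"})
        assert (labelled["label"] == "regionA").all()

    def test_mismatched_atlas_rejected(self):
        import nibabel as nib
        grid = cube_grid(12)
        table = self.table_for(grid)
        atlas = nib.Nifti1Image(np.ones((5, 5, 5), dtype=np.int16), grid.affine)
        with pytest.raises(ValueError):
            label_clusters(table, grid, atlas)
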