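import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from rangefc import (ClinicalVariable, CohortSpec, EffectRegion, make_brain_grid,
                     null_spec, region_voxels, simulate_bold,
                     simulate_motion_and_clinical, write_cohort)
from rangefc.fc import fisher_z


def small_spec(**kw):
    defaults = dict(n_patients=8, n_controls=8, grid_shape=(10, 20, 10),
                    voxel_size_mm=7.0, n_timepoints=60, rng_seed=7,
                    effect_regions=(), smoothing_fwhm_mm=8.0)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestBrainGrid:
    def test_default_grid_has_short_and_long_pairs(self):
        grid = make_brain_grid(CohortSpec())
        d = pdist(grid.coords_mm[::13])  # subsample for speed
        assert d.max() >= 108.0
        assert (d < 75.0).any() and (d >= 75.0).any()

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(grid_shape=(2, 2, 2))

    def test_default_voxel_count_matches_brute_force_ellipsoid(self):
        spec = CohortSpec()
        grid = make_brain_grid(spec)
        shape = np.array(spec.grid_shape)
        center = (shape - 1) / 2
        count = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    r2 = sum(((v - c) / c) ** 2 for v, c in zip((i, j, k), center))
                    count += r2 <= 1.0
        assert grid.voxel_count == count
        assert 500 <= grid.voxel_count <= 20000

    def test_mm_origin_at_grid_center(self):
        grid = make_brain_grid(CohortSpec())
        np.testing.assert_allclose(grid.coords_mm.mean(axis=0), 0.0, atol=1e-9)


class TestSimulateBold:
    def test_bitwise_deterministic(self):
        spec = small_spec()
        grid = make_brain_grid(spec)
        a = simulate_bold(spec, grid, "patient", subject_seed=3)
        b = simulate_bold(spec, grid, "patient", subject_seed=3)
        assert np.array_equal(a.data, b.data)
        c = simulate_bold(spec, grid, "patient", subject_seed=4)
        assert not np.array_equal(a.data, c.data)

    def test_too_few_timepoints_rejected(self):
        spec = small_spec(n_timepoints=20)
        grid = make_brain_grid(spec)
        with pytest.raises(ValueError):
            simulate_bold(spec, grid, "control", 0)

    def test_null_deltas_give_no_voxelwise_group_difference(self):
        regions = (
            EffectRegion("probe_local", (0.0, -21.0, 0.0), 14.0, "local", -0.4),
            EffectRegion("probe_distal", (0.0, 42.0, 0.0), 14.0, "distal", +0.4,
                         partner_center_mm=(0.0, -42.0, 0.0)),
        )
        spec = null_spec(small_spec(effect_regions=regions,
                                    n_patients=10, n_controls=10))
        grid = make_brain_grid(spec)
        from rangefc import compute_fc_strength
        sp_p = np.stack([compute_fc_strength(simulate_bold(spec, grid, "patient", i),
                                             grid).spfc for i in range(10)])
        sp_c = np.stack([compute_fc_strength(simulate_bold(spec, grid, "control",
                                                           100 + i), grid).spfc
                         for i in range(10)])
        t = stats.ttest_ind(sp_p, sp_c, axis=0, equal_var=True).statistic
        crit = stats.t.isf(0.0005, 18)  # two-sided alpha = 0.001
        assert (np.abs(t) < crit).mean() >= 0.99

    def test_negative_local_delta_lowers_within_region_coupling(self):
        region = EffectRegion("probe_local", (0.0, 0.0, 0.0), 14.0, "local", -0.4)
        spec = small_spec(effect_regions=(region,), n_timepoints=120)
        grid = make_brain_grid(spec)
        vox = region_voxels(grid, region.center_mm, region.radius_mm)
        assert len(vox) > 3

        def mean_within_z(group, seeds):
            zs = []
            for s in seeds:
                X = simulate_bold(spec, grid, group, s).data[:, vox]
                r = np.corrcoef(X.T)
                zs.append(fisher_z(r[np.triu_indices(len(vox), 1)]).mean())
            return np.mean(zs)

        z_pat = mean_within_z("patient", range(10))
        z_ctl = mean_within_z("control", range(50, 60))
        assert z_pat < z_ctl


class TestMotionAndClinical:
    def test_large_patient_sample_matches_severity_model(self):
        spec = small_spec(n_patients=1000, n_controls=2)
        _, subjects = simulate_motion_and_clinical(spec)
        ybocs = subjects.loc[subjects.group == "patient", "ybocs_total"]
        assert abs(ybocs.mean() - 24.90) < 0.6
        assert (subjects["ybocs_total"] >= 0).all()

    def test_zero_amplitude_motion_gives_zero_fd(self):
        spec = small_spec(motion_step_mm={"patient": 0.0, "control": 0.0})
        _, subjects = simulate_motion_and_clinical(spec)
        assert (subjects["mean_fd"] == 0.0).all()
        assert not subjects["excluded"].any()

    def test_injected_jump_triggers_exclusion(self):
        spec = small_spec(motion_exclusion_fraction=1.0)
        _, subjects = simulate_motion_and_clinical(spec)
        assert subjects["excluded"].all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ClinicalVariable(5.0, -1.0, 5.0, 1.0)

    def test_group_sex_ratio_configured(self):
        spec = small_spec(n_patients=400, n_controls=2)
        _, subjects = simulate_motion_and_clinical(spec)
        frac = (subjects.loc[subjects.group == "patient", "sex"] == "M").mean()
        assert abs(frac - 27 / 40) < 0.07

    def test_reproducible_from_seed(self):
        a = simulate_motion_and_clinical(small_spec())[1]
        b = simulate_motion_and_clinical(small_spec())[1]
        pd.testing.assert_frame_equal(a, b)


class TestCohortOnDisk:
    def test_written_cohort_reads_back(self, tmp_path):
        spec = small_spec(n_patients=2, n_controls=2, n_timepoints=40)
        subjects = write_cohort(spec, tmp_path)
        from rangefc import BoldSeries, BrainGrid
        grid = BrainGrid.from_nifti(tmp_path / "mask.nii.gz")
        assert grid.voxel_count > 0
        sid = subjects["subject_id"].iloc[0]
        series = BoldSeries.from_nifti(tmp_path / f"{sid}_bold.nii.gz", grid)
        assert series.data.shape == (40, grid.voxel_count)
        motion = np.loadtxt(tmp_path / f"{sid}_motion.txt")
        assert motion.shape == (40, 6)
        table = pd.read_csv(tmp_path / "subjects.tsv", sep="\t")
        assert list(table.columns[:3]) == ["subject_id", "group", "age"]
        assert {"mean_fd", "hama", "ybocs_total"} <= set(table.columns)
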