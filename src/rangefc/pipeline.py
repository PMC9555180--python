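"""End-to-end study runner: cohort -> FC maps -> group GLM -> GRF clusters.

Glue over the library modules so tests, scripts and the CLI can run the
whole analysis with one call.  BOLD series are simulated (or loaded),
converted to short/long-range positive FC-strength maps subject by subject
(series are never all held in memory), and each measure is tested
voxelwise with the covariate-adjusted group GLM followed by
random-field cluster correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm
from .cohort import CohortSpec, make_brain_grid, simulate_bold, simulate_motion_and_clinical
from .fc import DistanceModel, compute_fc_strength
from .grids import BrainGrid

POSITIVE_MEASURES = ("spfc", "lpfc")


@dataclass
class StudyResult:
    grid: BrainGrid
    subjects: pd.DataFrame                    # retained subjects only
    maps: dict[str, np.ndarray]               # measure -> subjects x V
    tmaps: dict[str, glm.TMap]
    smoothness: dict[str, glm.SmoothnessEstimate]
    cluster_tables: dict[str, pd.DataFrame]


def compute_cohort_maps(spec: CohortSpec, grid: BrainGrid,
                        subjects: pd.DataFrame,
                        block_size: int = 512) -> dict[str, np.ndarray]:
    """Simulate each retained subject and stack the four strength maps."""
    model = DistanceModel(threshold_mm=spec.distance_threshold_mm)
    stacks: dict[str, list] = {m: [] for m in ("spfc", "lpfc", "snfc", "lnfc")}
    for idx, row in subjects.iterrows():
        series = simulate_bold(spec, grid, row["group"], subject_seed=int(idx))
        maps = compute_fc_strength(series, grid, model, block_size=block_size)
        for m in stacks:
            stacks[m].append(getattr(maps, m))
    return {m: np.vstack(v) for m, v in stacks.items()}


def run_study(spec: CohortSpec, measures=POSITIVE_MEASURES,
              voxel_p: float = glm.DEFAULT_VOXEL_P,
              cluster_p: float = glm.DEFAULT_CLUSTER_P,
              covariates=glm.DEFAULT_COVARIATES,
              block_size: int = 512) -> StudyResult:
    """Simulate the cohort and run the group analysis on each FC measure.

    Subjects exceeding the motion-exclusion rule are dropped before any
    imaging computation, mirroring the usual quality-control order.
    """
    grid = make_brain_grid(spec)
    _, subjects = simulate_motion_and_clinical(spec)
    retained = subjects[~subjects["excluded"]]
    maps = compute_cohort_maps(spec, grid, retained, block_size=block_size)
    retained = retained.reset_index(drop=True)

    design, _ = glm.build_design_matrix(retained, covariates=covariates)
    tmaps, smooths, tables = {}, {}, {}
    for measure in measures:
        tmap, resid = glm.fit_voxelwise_glm(maps[measure], design)
        smooth = glm.estimate_smoothness(resid, grid)
        tmaps[measure] = tmap
        smooths[measure] = smooth
        tables[measure] = glm.grf_cluster_correct(tmap, smooth, grid,
                                                  voxel_p=voxel_p, cluster_p=cluster_p)
    return StudyResult(grid=grid, subjects=retained, maps=maps,
                       tmaps=tmaps, smoothness=smooths, cluster_tables=tables)


def cluster_member_voxels(result: StudyResult, measure: str,
                          table_row: int,
                          voxel_p: float = glm.DEFAULT_VOXEL_P) -> np.ndarray:
    """In-mask voxel indices belonging to one surviving cluster.

    The cluster membership is rebuilt from the thresholded (Gaussianized)
    t map with the same 26-connectivity used for correction.
    """
    from nibabel.affines import apply_affine
    from scipy import ndimage, stats

    table = result.cluster_tables[measure]
    row = table.iloc[table_row]
    grid = result.grid
    tmap = result.tmaps[measure]
    u = stats.norm.isf(voxel_p)
    field = grid.vector_to_volume(row["tail"] * glm._gaussianize_t(tmap.t, tmap.df),
                                  fill=-np.inf)
    labels, _ = ndimage.label(field > u, structure=glm._connectivity_structure(26))
    inv = np.linalg.inv(grid.affine)
    peak_ijk = np.rint(apply_affine(inv, [[row["peak_x_mm"], row["peak_y_mm"],
                                           row["peak_z_mm"]]])[0]).astype(int)
    cluster_id = labels[tuple(peak_ijk)]
    member_lin = np.flatnonzero((labels == cluster_id).ravel())
    return np.searchsorted(grid.index_table, member_lin)


def cluster_mean_features(result: StudyResult, measure: str,
                          table_row: int) -> np.ndarray:
    """Subjects x 1 cluster-mean feature for one surviving cluster."""
    from .svm import extract_region_features

    members = cluster_member_voxels(result, measure, table_row)
    return extract_region_features(result.maps[measure], members)


def recovery_report(result: StudyResult, spec) -> dict:
    """Match surviving clusters against the planted effect regions.

    A planted sphere (an effect region's center, and its partner for
    distal coupling) counts as *recovered* when at least one surviving
    cluster of any analysed measure overlaps it and the cluster's tail
    matches the sign of the planted delta.  A cluster overlapping no
    planted sphere is a false positive.
    """
    from .cohort import region_voxels

    planted = []
    for region in spec.effect_regions:
        sign = int(np.sign(region.patient_coupling_delta)) or 1
        planted.append((f"{region.name}:center",
                        region_voxels(result.grid, region.center_mm, region.radius_mm),
                        sign))
        if region.partner_center_mm is not None:
            planted.append((f"{region.name}:partner",
                            region_voxels(result.grid, region.partner_center_mm,
                                          region.radius_mm), sign))
    recovered = {name: False for name, _, _ in planted}
    false_positives = 0
    for measure, table in result.cluster_tables.items():
        for i in range(len(table)):
            tail = int(table.iloc[i]["tail"])
            members = set(cluster_member_voxels(result, measure, i).tolist())
            hit = False
            for name, vox, sign in planted:
                if members & set(vox.tolist()):
                    hit = True
                    if tail == sign:
                        recovered[name] = True
            if not hit:
                false_positives += 1
    return {"recovered": recovered,
            "n_planted": len(planted),
            "n_recovered": int(sum(recovered.values())),
            "false_positives": false_positives}
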