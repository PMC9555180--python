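"""Voxelwise group GLM and Gaussian-random-field cluster-extent inference.

Group differences in FC-strength maps are tested with an ordinary
least-squares model per voxel (intercept, group indicator coded +1 patient /
-1 control, centered nuisance covariates), giving a t map.  Multiple
comparisons are controlled with random-field theory: the residuals' spatial
smoothness (per-axis FWHM) is estimated from standardized residual first
differences, the t map is Gaussianized, thresholded at the voxel-forming
p value, and each 26-connected suprathreshold cluster receives a corrected
p from the standard cluster-extent formula

    P(max extent >= k) = 1 - exp(-E[m] * exp(-beta * k_resels^(2/3)))

with E[m] the expected cluster count from the 3D Euler-characteristic
density and beta matched to the expected suprathreshold volume.  Two-sided
inference runs the positive and negative tails separately at the voxel
threshold and Bonferroni-splits the cluster-level alpha across tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nibabel.affines import apply_affine
from scipy import ndimage, stats

from .grids import BrainGrid

DEFAULT_COVARIATES = ("age", "sex", "education_years", "mean_fd", "hamd17", "hama")
DEFAULT_VOXEL_P = 0.001
DEFAULT_CLUSTER_P = 0.05

CLUSTER_TABLE_COLUMNS = ["label", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                         "n_voxels", "peak_t", "corrected_p", "tail"]


@dataclass
class TMap:
    t: np.ndarray
    df: int
    contrast: str = "group"


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray            # per-axis FWHM
    resel_count: float
    search_volume_voxels: int


def build_design_matrix(subjects: pd.DataFrame,
                        covariates=DEFAULT_COVARIATES,
                        patient_label: str = "patient",
                        center: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, group (+1 patient / -1 control), covariates.

    ``sex`` columns holding 'M'/'F' strings are coded 1/0.  Covariates are
    mean-centered by default (leaves the group t unchanged, keeps the
    intercept interpretable).
    """
    n = len(subjects)
    group = np.where(subjects["group"].to_numpy() == patient_label, 1.0, -1.0)
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    for cov in covariates:
        vals = subjects[cov]
        if vals.dtype == object:
            vals = vals.map({"M": 1.0, "F": 0.0})
            if vals.isna().any():
                raise ValueError(f"cannot numerically code covariate {cov!r}")
        x = vals.to_numpy(dtype=float)
        if center:
            x = x - x.mean()
        cols.append(x)
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if n <= X.shape[1] + 2:
        raise ValueError("too few subjects for the requested design")
    return X, names


def fit_voxelwise_glm(maps: np.ndarray, design: np.ndarray,
                      contrast_col: int = 1,
                      contrast_name: str = "group") -> tuple[TMap, np.ndarray]:
    """OLS per voxel; t statistic for one design column; residuals returned.

    ``maps`` is subjects x V.  The t map equals the pooled two-sample t
    statistic when the design is intercept + group only.
    """
    Y = np.asarray(maps, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("maps and design disagree on subject count")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    df = n - rank
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[contrast_col, contrast_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[contrast_col] / se
    t[~np.isfinite(t)] = 0.0    # zero-variance voxels
    return TMap(t=t, df=df, contrast=contrast_name), resid


def estimate_smoothness(residuals: np.ndarray, grid: BrainGrid) -> SmoothnessEstimate:
    """Per-axis FWHM from the variance of standardized residual differences.

    Residual maps (subjects x V) are standardized voxelwise; for each axis
    the variance of first differences between in-mask neighbours, pooled
    over subjects, gives the roughness lambda_d, and
    FWHM_d = voxel_size_d * sqrt(4 ln 2 / lambda_d).
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.ndim != 2 or resid.shape[1] != grid.voxel_count:
        raise ValueError("residuals must be subjects x V on the grid")
    if resid.shape[0] < 10:
        raise ValueError("need at least 10 residual maps to estimate smoothness")
    ss = np.sqrt((resid ** 2).sum(axis=0))
    ok = ss > 0
    if not ok.any():
        raise ValueError("residuals are identically zero")
    u = resid / np.where(ok, ss, 1.0)
    u[:, ~ok] = np.nan

    # Scatter standardized residuals into volumes once (subjects stacked).
    n = resid.shape[0]
    vols = np.full((n,) + grid.mask.shape, np.nan)
    flat = vols.reshape(n, -1)
    flat[:, grid.index_table] = u

    voxel_sizes = grid.voxel_sizes_mm
    fwhm = np.empty(3)
    for axis in range(3):
        d = np.diff(vols, axis=axis + 1)
        d = d[np.isfinite(d)]
        if d.size == 0:
            raise ValueError(f"mask has no neighbouring voxel pairs along axis {axis}")
        # sum over subjects of squared diffs per pair == per-pair variance
        # estimate because voxelwise standardization fixes unit sum of squares
        lam = float((d ** 2).sum()) / (d.size / n)
        if lam <= 0:
            raise ValueError("constant residual field: smoothness undefined")
        fwhm[axis] = voxel_sizes[axis] * np.sqrt(4.0 * np.log(2.0) / lam)
    resel_count = grid.voxel_count * grid.voxel_volume_mm3 / float(np.prod(fwhm))
    return SmoothnessEstimate(fwhm_mm=fwhm, resel_count=resel_count,
                              search_volume_voxels=grid.voxel_count)


def _ec_density_3d(u: float) -> float:
    """3D Euler-characteristic density of a unit Gaussian field at height u."""
    return ((4.0 * np.log(2.0)) ** 1.5 / (2.0 * np.pi) ** 2
            * (u * u - 1.0) * np.exp(-0.5 * u * u))


def _gaussianize_t(t: np.ndarray, df: int) -> np.ndarray:
    at = np.abs(t)
    z = stats.norm.isf(stats.t.sf(at, df))
    z = np.clip(z, None, 38.0)          # sf underflows past ~38 sigma
    return np.sign(t) * z


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order)


def grf_cluster_correct(tmap: TMap, smooth: SmoothnessEstimate, grid: BrainGrid,
                        voxel_p: float = DEFAULT_VOXEL_P,
                        cluster_p: float = DEFAULT_CLUSTER_P,
                        connectivity: int = 26,
                        two_sided: bool = True) -> pd.DataFrame:
    """Cluster table of suprathreshold clusters surviving GRF correction.

    Columns: label (peak-coordinate string), peak x/y/z (mm), voxel count,
    peak t, cluster-level corrected p, tail (+1/-1); sorted by corrected p.
    """
    if smooth.resel_count <= 0 or not np.isfinite(smooth.resel_count):
        raise ValueError("resel count must be positive and finite")
    u = stats.norm.isf(voxel_p)
    if not np.isfinite(u):
        raise ValueError("voxel_p yields a non-finite threshold")
    z = _gaussianize_t(tmap.t, tmap.df)
    structure = _connectivity_structure(connectivity)

    em = smooth.resel_count * _ec_density_3d(u)          # expected clusters
    en = smooth.resel_count * stats.norm.sf(u)           # expected volume, resels
    beta = (math.gamma(2.5) * max(em, 1e-300) / max(en, 1e-300)) ** (2.0 / 3.0)
    voxels_per_resel = float(np.prod(smooth.fwhm_mm)) / grid.voxel_volume_mm3

    n_tails = 2 if two_sided else 1
    t_flat = grid.vector_to_volume(tmap.t).ravel()
    rows = []
    for tail in ((1, -1) if two_sided else (1,)):
        field = grid.vector_to_volume(tail * z, fill=-np.inf)
        labels, n_clusters = ndimage.label(field > u, structure=structure)
        for c in range(1, n_clusters + 1):
            cluster_lin = np.flatnonzero((labels == c).ravel())
            k = cluster_lin.size
            k_resels = k / voxels_per_resel
            p_corr = 1.0 - np.exp(-em * np.exp(-beta * k_resels ** (2.0 / 3.0)))
            p_corr = min(1.0, n_tails * p_corr)          # Bonferroni across tails
            if p_corr >= cluster_p:
                continue
            peak_lin = cluster_lin[np.argmax(field.ravel()[cluster_lin])]
            peak_ijk = np.unravel_index(peak_lin, grid.mask.shape)
            peak_mm = apply_affine(grid.affine, np.array(peak_ijk))
            rows.append({
                "label": f"({peak_mm[0]:.0f}, {peak_mm[1]:.0f}, {peak_mm[2]:.0f})",
                "peak_x_mm": peak_mm[0], "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2], "n_voxels": int(k),
                "peak_t": float(t_flat[peak_lin]), "corrected_p": p_corr, "tail": tail,
            })
    table = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    return table.sort_values("corrected_p", kind="stable").reset_index(drop=True)


def label_clusters(table: pd.DataFrame, grid: BrainGrid,
                   atlas_img=None, atlas_names: dict | None = None) -> pd.DataFrame:
    """Attach nearest-region labels from an integer atlas image, if given.

    Without an atlas the peak-coordinate strings already present are kept.
    """
    if atlas_img is None:
        return table.copy()
    import nibabel as nib

    img = atlas_img if hasattr(atlas_img, "dataobj") else nib.load(str(atlas_img))
    atlas = np.asanyarray(img.dataobj)
    if atlas.shape != grid.mask.shape or not np.allclose(img.affine, grid.affine):
        raise ValueError("atlas grid does not match the study grid")
    labeled = np.argwhere(atlas > 0)
    if labeled.size == 0:
        raise ValueError("atlas has no labeled voxels")
    labeled_mm = apply_affine(grid.affine, labeled)
    out = table.copy()
    names = []
    for _, row in out.iterrows():
        peak = np.array([row.peak_x_mm, row.peak_y_mm, row.peak_z_mm])
        nearest = labeled[np.argmin(((labeled_mm - peak) ** 2).sum(axis=1))]
        code = int(atlas[tuple(nearest)])
        names.append(atlas_names.get(code, str(code)) if atlas_names else str(code))
    out["label"] = names
    return out
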