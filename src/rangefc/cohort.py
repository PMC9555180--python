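"""Synthetic two-group resting-state cohort generator.

Emulates a post-preprocessing OCD-vs-control study: an ellipsoidal
"brain" mask on an MNI-like grid, per-subject BOLD series with spatially
smooth, temporally autocorrelated noise, group differences planted as
changes in latent-factor coupling, smooth head-motion traces, and a
clinical table whose per-group distributions follow the demographics of a
typical medication-free OCD sample (n = 40 patients / 38 retained
controls; Y-BOCS, 17-HAMD, HAMA severity scores).

Signal model: each effect region owns a unit-variance AR(1) latent time
course; member voxels load on it with a baseline loading, shifted by
``patient_coupling_delta`` in patients.  ``local`` regions (all pairwise
distances under the short/long split) modulate short-range coupling;
``distal`` regions share their factor with a partner sphere more than the
split distance away, modulating long-range coupling.  Voxelwise AR(1)
noise is added and each volume is Gaussian-smoothed, so downstream maps
have the spatial smoothness random-field inference assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import BoldSeries, BrainGrid
from .preproc import MotionTrace, apply_exclusion_rule, framewise_displacement

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_CLINICAL_STREAM_OFFSET = 1_000_003   # keeps clinical rng clear of subject seeds


@dataclass(frozen=True)
class EffectRegion:
    """A sphere of voxels whose latent coupling differs between groups."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    coupling_kind: str                       # "local" | "distal"
    patient_coupling_delta: float
    partner_center_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.coupling_kind not in ("local", "distal"):
            raise ValueError("coupling_kind must be 'local' or 'distal'")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not np.isfinite(self.patient_coupling_delta):
            raise ValueError("patient_coupling_delta must be finite")
        if self.coupling_kind == "distal":
            if self.partner_center_mm is None:
                raise ValueError("distal region needs a partner_center_mm")


@dataclass(frozen=True)
class ClinicalVariable:
    """Truncated-normal (at zero) group models for one clinical score."""

    patient_mean: float
    patient_sd: float
    control_mean: float
    control_sd: float
    truncate_at_zero: bool = True

    def __post_init__(self):
        if self.patient_sd < 0 or self.control_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def default_effect_regions() -> tuple[EffectRegion, ...]:
    """Planted effects mirroring the qualitative group differences studied:

    a sensorimotor-like region with *lower* local (short-range) coupling in
    patients, and two long-range pairs (thalamo-occipital-like and
    parieto-cerebellar-like) with *higher* distal coupling in patients.
    Centers lie on the default 6 mm grid, inside the default ellipsoid.
    """
    return (
        EffectRegion("sensorimotor_local", (-27.0, -15.0, 27.0), 12.0,
                     "local", -0.7),
        EffectRegion("thalamic_distal", (3.0, 45.0, -3.0), 12.0,
                     "distal", +0.7, partner_center_mm=(3.0, -45.0, -3.0)),
        EffectRegion("parieto_cerebellar_distal", (27.0, 27.0, -21.0), 12.0,
                     "distal", +0.7, partner_center_mm=(-27.0, -39.0, 15.0)),
    )


def default_clinical_model() -> dict[str, ClinicalVariable]:
    """Group means/SDs for the clinical table of a typical OCD sample."""
    return {
        "age": ClinicalVariable(27.28, 8.16, 27.18, 8.33),
        "education_years": ClinicalVariable(13.40, 2.87, 13.74, 3.03),
        "ybocs_total": ClinicalVariable(24.90, 5.73, 1.13, 0.88),
        "ybocs_obsessive": ClinicalVariable(12.85, 4.25, 0.37, 0.49),
        "ybocs_compulsive": ClinicalVariable(12.05, 4.62, 0.74, 0.72),
        "hamd17": ClinicalVariable(8.05, 4.40, 1.45, 0.95),
        "hama": ClinicalVariable(10.83, 6.55, 1.16, 1.00),
    }


@dataclass
class CohortSpec:
    """Full description of a synthetic study; defaults are the study conditions."""

    n_patients: int = 40
    n_controls: int = 38
    grid_shape: tuple[int, int, int] = (18, 22, 18)
    voxel_size_mm: float = 6.0
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    ar1_coefficient: float = 0.3
    smoothing_fwhm_mm: float = 8.0
    effect_regions: tuple[EffectRegion, ...] = field(default_factory=default_effect_regions)
    rng_seed: int = 0
    clinical_model: dict[str, ClinicalVariable] = field(default_factory=default_clinical_model)
    baseline_loading: float = 1.0
    distance_threshold_mm: float = 75.0
    # group male fractions for the sex column (27/40 and 25/38)
    patient_male_fraction: float = 27.0 / 40.0
    control_male_fraction: float = 25.0 / 38.0
    # motion: random-walk step SD per volume (translations, mm); rotation
    # steps are step/50 rad so both terms contribute equally to FD
    motion_step_mm: dict = field(default_factory=lambda: {"patient": 0.0084, "control": 0.0063})
    motion_subject_cv: float = 0.45          # lognormal spread of per-subject amplitude
    motion_exclusion_fraction: float = 0.0   # fraction given a >2 mm jump

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if min(self.grid_shape) < 3:
            raise ValueError("each grid axis needs at least 3 voxels")
        if self.voxel_size_mm <= 0 or self.tr_seconds <= 0:
            raise ValueError("voxel size and TR must be positive")
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be non-negative")
        extents = np.array(self.grid_shape) * self.voxel_size_mm
        if extents.max() <= 108.0:
            raise ValueError("grid too small: need one axis extent above 108 mm "
                             "so pairs beyond the distance split exist")
        for region in self.effect_regions:
            if region.coupling_kind == "distal":
                d = np.linalg.norm(np.subtract(region.center_mm, region.partner_center_mm))
                if d <= self.distance_threshold_mm:
                    raise ValueError(f"distal region {region.name!r}: partner only "
                                     f"{d:.1f} mm away")
            else:
                if 2.0 * region.radius_mm >= self.distance_threshold_mm:
                    raise ValueError(f"local region {region.name!r} wider than the "
                                     "distance split")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"patient": self.n_patients, "control": self.n_controls}


def make_brain_grid(spec: CohortSpec) -> BrainGrid:
    """Ellipsoidal mask centered in the grid, mm origin at the grid center."""
    shape = np.asarray(spec.grid_shape)
    center = (shape - 1) / 2.0
    semi_axes = (shape - 1) / 2.0
    idx = np.indices(spec.grid_shape)
    r2 = sum(((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    mask = r2 <= 1.0
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -center * spec.voxel_size_mm
    return BrainGrid(mask=mask, affine=affine)


def _ar1_series(rng: np.random.Generator, phi: float, shape: tuple) -> np.ndarray:
    """Unit-variance stationary AR(1) noise, time along the first axis."""
    T = shape[0]
    eps = rng.standard_normal(shape)
    out = np.empty(shape)
    out[0] = eps[0]
    innov = np.sqrt(1.0 - phi * phi)
    for t in range(1, T):
        out[t] = phi * out[t - 1] + innov * eps[t]
    return out


def region_voxels(grid: BrainGrid, center_mm, radius_mm: float) -> np.ndarray:
    """Indices (into the grid's voxel ordering) of a spherical region."""
    d = np.linalg.norm(grid.coords_mm - np.asarray(center_mm, dtype=float), axis=1)
    return np.flatnonzero(d <= radius_mm)


def _loading_matrix(spec: CohortSpec, grid: BrainGrid, group: str) -> np.ndarray:
    V = grid.voxel_count
    regions = spec.effect_regions
    lam = np.zeros((V, len(regions)))
    for k, region in enumerate(regions):
        loading = spec.baseline_loading
        if group == "patient":
            loading = loading + region.patient_coupling_delta
        members = region_voxels(grid, region.center_mm, region.radius_mm)
        if members.size == 0:
            raise ValueError(f"region {region.name!r} covers no in-mask voxels")
        lam[members, k] = loading
        if region.coupling_kind == "distal":
            partners = region_voxels(grid, region.partner_center_mm, region.radius_mm)
            if partners.size == 0:
                raise ValueError(f"partner of region {region.name!r} covers no voxels")
            # coupling is a property of the pair: the delta shifts both ends
            lam[partners, k] = loading
    if not np.isfinite(lam).all():
        raise ValueError("non-finite loadings")
    return lam


def simulate_bold(spec: CohortSpec, grid: BrainGrid, group: str,
                  subject_seed: int) -> BoldSeries:
    """One subject's BOLD series; bit-reproducible from (rng_seed, subject_seed)."""
    if group not in ("patient", "control"):
        raise ValueError("group must be 'patient' or 'control'")
    if spec.n_timepoints < 30:
        raise ValueError("need at least 30 timepoints for stable correlations")
    rng = np.random.default_rng(spec.rng_seed + subject_seed)
    T, V = spec.n_timepoints, grid.voxel_count

    lam = _loading_matrix(spec, grid, group)
    factors = _ar1_series(rng, spec.ar1_coefficient, (T, lam.shape[1]))
    data = factors @ lam.T + _ar1_series(rng, spec.ar1_coefficient, (T, V))

    if spec.smoothing_fwhm_mm > 0:
        sigma_vox = spec.smoothing_fwhm_mm * GAUSS_FWHM_TO_SIGMA / spec.voxel_size_mm
        vols = np.zeros((T,) + grid.mask.shape)
        vols.reshape(T, -1)[:, grid.index_table] = data
        vols = ndimage.gaussian_filter(vols, sigma=(0.0, sigma_vox, sigma_vox, sigma_vox))
        data = vols.reshape(T, -1)[:, grid.index_table]

    return BoldSeries(data=data, tr_seconds=spec.tr_seconds,
                      subject_id=f"sub-{subject_seed:03d}")


def _sample_clinical(rng: np.random.Generator, model: ClinicalVariable,
                     group: str, size: int) -> np.ndarray:
    mean, sd = ((model.patient_mean, model.patient_sd) if group == "patient"
                else (model.control_mean, model.control_sd))
    if sd == 0:
        return np.full(size, mean)
    if model.truncate_at_zero:
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                                   random_state=rng)
    return rng.normal(mean, sd, size)


def simulate_motion_and_clinical(spec: CohortSpec) -> tuple[list[MotionTrace], pd.DataFrame]:
    """Motion traces (smooth random walks) and the subject table.

    Subjects are ordered patients first, then controls, matching the
    subject seeds used by :func:`simulate_bold` (seed = subject index).
    A ``motion_exclusion_fraction`` of subjects receives a 3 mm translation
    jump so the exclusion rule has something to catch.
    """
    rng = np.random.default_rng(spec.rng_seed + _CLINICAL_STREAM_OFFSET)
    T = spec.n_timepoints
    rows, traces = [], []
    index = 0
    for group, n in spec.group_sizes.items():
        clin = {name: _sample_clinical(rng, model, group, n)
                for name, model in spec.clinical_model.items()}
        male_frac = (spec.patient_male_fraction if group == "patient"
                     else spec.control_male_fraction)
        sex = np.where(rng.random(n) < male_frac, "M", "F")
        step = spec.motion_step_mm[group]
        for i in range(n):
            amp = step * rng.lognormal(0.0, spec.motion_subject_cv)
            increments = np.column_stack([
                rng.normal(0.0, amp, (T, 3)),
                rng.normal(0.0, amp / 50.0, (T, 3)),
            ])
            increments[0] = 0.0
            params = np.cumsum(increments, axis=0)
            if rng.random() < spec.motion_exclusion_fraction:
                params[T // 2:, 0] += 3.0        # injected gross movement
            trace = framewise_displacement(params)
            traces.append(trace)
            rows.append({
                "subject_id": f"sub-{index:03d}", "group": group,
                "age": clin["age"][i], "sex": sex[i],
                "education_years": clin["education_years"][i],
                "ybocs_total": clin["ybocs_total"][i],
                "ybocs_obsessive": clin["ybocs_obsessive"][i],
                "ybocs_compulsive": clin["ybocs_compulsive"][i],
                "hamd17": clin["hamd17"][i], "hama": clin["hama"][i],
                "mean_fd": trace.mean_fd,
                "excluded": apply_exclusion_rule(params),
            })
            index += 1
    return traces, pd.DataFrame(rows)


def null_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with every planted coupling delta set to zero."""
    regions = tuple(replace(r, patient_coupling_delta=0.0) for r in spec.effect_regions)
    return replace(spec, effect_regions=regions)


def write_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Materialise the cohort on disk: mask, 4D series, motion, subject TSV."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = make_brain_grid(spec)
    grid.save(out / "mask.nii.gz")
    traces, subjects = simulate_motion_and_clinical(spec)
    groups = subjects["group"].tolist()
    for idx, (trace, group) in enumerate(zip(traces, groups)):
        sid = subjects["subject_id"].iloc[idx]
        series = simulate_bold(spec, grid, group, subject_seed=idx)
        series.save(out / f"{sid}_bold.nii.gz", grid)
        np.savetxt(out / f"{sid}_motion.txt", trace.params, fmt="%.8f")
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    return subjects
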