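"""Motion summaries, subject exclusion, and residual time-series cleaning.

Head motion is summarised per volume as Power-style framewise displacement
(FD): the sum of absolute backward differences of the three translations
(mm) plus, for the three rotations (radians), the arc length swept on a
sphere of configurable radius (default 50 mm).  Subjects are excluded when
any realignment parameter exceeds 2 mm translation or 2 degrees rotation.

``clean_series`` performs the minimal residual preprocessing expected before
FC computation on data already in template space: linear detrend, nuisance
(confound) regression and band-pass filtering, applied as one simultaneous
least-squares projection (discrete sine/cosine regressors for out-of-band
frequencies), so the operation is a projection and hence exactly idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BoldSeries

DEFAULT_ROTATION_RADIUS_MM = 50.0
DEFAULT_BAND_HZ = (0.01, 0.08)
EXCLUSION_TRANSLATION_MM = 2.0
EXCLUSION_ROTATION_DEG = 2.0


@dataclass
class MotionTrace:
    """Six rigid-body parameters per volume plus the derived FD series."""

    params: np.ndarray      # T x 6: translations mm, rotations radians
    fd: np.ndarray          # T, fd[0] = 0
    mean_fd: float

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]


def framewise_displacement(params: np.ndarray,
                           rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM) -> MotionTrace:
    """Power-style scalar FD from T x 6 realignment parameters."""
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be a T x 6 array")
    diffs = np.abs(np.diff(params, axis=0))
    fd = np.zeros(params.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + rotation_radius_mm * diffs[:, 3:].sum(axis=1)
    return MotionTrace(params=params, fd=fd, mean_fd=float(fd.mean()))


def apply_exclusion_rule(params: np.ndarray,
                         max_translation_mm: float = EXCLUSION_TRANSLATION_MM,
                         max_rotation_deg: float = EXCLUSION_ROTATION_DEG) -> bool:
    """True if the subject exceeds the motion-exclusion rule.

    Excluded iff absolute translation on any axis exceeds ``max_translation_mm``
    or absolute rotation around any axis exceeds ``max_rotation_deg``
    (rotations supplied in radians; the threshold is converted internally).
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be a T x 6 array")
    max_rot_rad = np.deg2rad(max_rotation_deg)
    return bool(np.abs(params[:, :3]).max() > max_translation_mm
                or np.abs(params[:, 3:]).max() > max_rot_rad)


def read_motion_params(path) -> np.ndarray:
    params = np.loadtxt(str(path), ndmin=2)
    if params.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return params


def write_motion_params(path, params: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(params, dtype=float), fmt="%.8f")


def _bandpass_regressors(n_timepoints: int, tr_seconds: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Sine/cosine pairs at DFT frequencies outside the pass band."""
    low, high = band
    if not (0 <= low < high):
        raise ValueError("band must satisfy 0 <= low < high")
    t = np.arange(n_timepoints)
    cols = []
    for k in range(1, n_timepoints // 2 + 1):
        f = k / (n_timepoints * tr_seconds)
        if low <= f <= high:
            continue
        phase = 2.0 * np.pi * k * t / n_timepoints
        cols.append(np.cos(phase))
        if 2 * k < n_timepoints:  # sine at Nyquist is identically ~0
            cols.append(np.sin(phase))
    if not cols:
        return np.empty((n_timepoints, 0))
    return np.column_stack(cols)


def clean_series(series: BoldSeries, confounds: np.ndarray | None = None,
                 band: tuple[float, float] | None = DEFAULT_BAND_HZ,
                 detrend: bool = True) -> BoldSeries:
    """Detrend, regress out confounds and band-pass in one projection.

    The nuisance design stacks an intercept, a linear trend (if ``detrend``),
    the confound columns, and out-of-band discrete Fourier regressors (if
    ``band`` is given).  The cleaned series is the least-squares residual, an
    orthogonal projection — applying ``clean_series`` twice with the same
    arguments changes nothing beyond round-off.
    """
    T = series.n_timepoints
    cols = [np.ones(T)]
    if detrend:
        cols.append(np.linspace(-1.0, 1.0, T))
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != T:
            raise ValueError("confounds must have one row per timepoint")
        if confounds.shape[1] >= T:
            raise ValueError("more confound columns than timepoints: design overdetermined")
        cols.append(confounds)
    if band is not None:
        cols.append(_bandpass_regressors(T, series.tr_seconds, band))
    design = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    if design.shape[1] >= T:
        raise ValueError("nuisance design has as many columns as timepoints")
    q, _ = np.linalg.qr(design)
    resid = series.data - q @ (q.T @ series.data)
    return BoldSeries(data=resid, tr_seconds=series.tr_seconds, subject_id=series.subject_id)
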