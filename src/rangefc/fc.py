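"""Distance-resolved functional-connectivity strength.

The core statistic: for every in-mask voxel i, Pearson-correlate its time
series with every other in-mask voxel j, Fisher z-transform the
correlations, and sum z values over j separated by Euclidean distance
D_ij between voxel centers (mm).  Pairs with D below the threshold
(default 75 mm) contribute to the short-range strength, pairs at or above
it to the long-range strength; positive and negative z are accumulated
separately, yielding four per-voxel maps:

    spfc_i = sum_{j != i, D_ij <  thr} z_ij [z_ij > 0]
    lpfc_i = sum_{j != i, D_ij >= thr} z_ij [z_ij > 0]
    snfc_i, lnfc_i : the analogous negative parts

so spfc + snfc + lpfc + lnfc is the total FC strength of the voxel and the
positive short/long split partitions the total positive strength exactly.
The computation runs in voxel blocks; the result is block-size independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .grids import BoldSeries, BrainGrid

DEFAULT_THRESHOLD_MM = 75.0
R_CLAMP = 1e-7


def fisher_z(r):
    """Fisher variance-stabilizing transform z = atanh(r) = 0.5 ln((1+r)/(1-r)).

    Correlations of magnitude 1 (degenerate, e.g. duplicated time series)
    are clamped to 1 - 1e-7 so the result stays finite.
    """
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("correlations must be finite")
    if np.abs(r).max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -1.0 + R_CLAMP, 1.0 - R_CLAMP))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DistanceModel:
    """Euclidean split of voxel pairs into short (< threshold) and long (>=)."""

    threshold_mm: float = DEFAULT_THRESHOLD_MM

    def __post_init__(self):
        if self.threshold_mm <= 0:
            raise ValueError("threshold_mm must be positive")


class PairwiseDistances:
    """On-demand block accessor for Euclidean voxel-center distances (mm)."""

    def __init__(self, grid: BrainGrid):
        self._coords = grid.coords_mm

    @property
    def n_voxels(self) -> int:
        return self._coords.shape[0]

    def block(self, start: int, stop: int) -> np.ndarray:
        """Distances from voxels [start:stop) to all voxels: (stop-start) x V."""
        return cdist(self._coords[start:stop], self._coords)

    def row(self, i: int) -> np.ndarray:
        return self.block(i, i + 1)[0]


@dataclass
class FCStrengthMaps:
    """Per-voxel short/long-range positive/negative FC strength vectors."""

    spfc: np.ndarray
    lpfc: np.ndarray
    snfc: np.ndarray
    lnfc: np.ndarray
    threshold_mm: float = DEFAULT_THRESHOLD_MM
    subject_id: str = ""

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"spfc": self.spfc, "lpfc": self.lpfc, "snfc": self.snfc, "lnfc": self.lnfc}


def compute_fc_strength(series: BoldSeries, grid: BrainGrid,
                        model: DistanceModel | None = None,
                        block_size: int = 512) -> FCStrengthMaps:
    """Compute the four FC-strength maps for one subject.

    Correlations are computed from standardized time series in voxel blocks
    (``block_size`` rows of the correlation matrix at a time); the full
    V x V matrix never needs to exist.  Voxels with zero temporal variance
    contribute nothing and receive all-zero maps (with a warning).
    """
    model = model or DistanceModel()
    X = series.data
    T, V = X.shape
    if V != grid.voxel_count:
        raise ValueError("series and grid disagree on voxel count")
    if T < 3:
        raise ValueError("need at least 3 timepoints for correlation")

    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    # constant columns center to rounding noise, not exact zero
    dead = norms <= np.finfo(float).eps * T * np.maximum(1.0, np.abs(X).max(axis=0))
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance voxels get all-zero strength maps")
        norms = np.where(dead, 1.0, norms)
    Xn = Xc / norms
    Xn[:, dead] = 0.0

    dist = PairwiseDistances(grid)
    thr = model.threshold_mm
    spfc = np.zeros(V)
    lpfc = np.zeros(V)
    snfc = np.zeros(V)
    lnfc = np.zeros(V)

    for start in range(0, V, block_size):
        stop = min(start + block_size, V)
        r = Xn[:, start:stop].T @ Xn            # (b, V) correlation rows
        z = np.arctanh(np.clip(r, -1.0 + R_CLAMP, 1.0 - R_CLAMP))
        b = stop - start
        z[np.arange(b), np.arange(start, stop)] = 0.0   # exclude self pair
        short = dist.block(start, stop) < thr
        pos = z > 0.0
        neg = z < 0.0
        spfc[start:stop] = np.where(pos & short, z, 0.0).sum(axis=1)
        lpfc[start:stop] = np.where(pos & ~short, z, 0.0).sum(axis=1)
        snfc[start:stop] = np.where(neg & short, z, 0.0).sum(axis=1)
        lnfc[start:stop] = np.where(neg & ~short, z, 0.0).sum(axis=1)

    return FCStrengthMaps(spfc=spfc, lpfc=lpfc, snfc=snfc, lnfc=lnfc,
                          threshold_mm=thr, subject_id=series.subject_id)


def strength_from_z(z_values, distances_mm, threshold_mm: float = DEFAULT_THRESHOLD_MM) -> FCStrengthMaps:
    """FC strength of a single voxel from given z values and pair distances.

    Entry point for worked examples where the Fisher-z correlations of one
    voxel to its neighbours are known directly; returns scalar maps.
    """
    z = np.asarray(z_values, dtype=float)
    d = np.asarray(distances_mm, dtype=float)
    if z.shape != d.shape:
        raise ValueError("z_values and distances_mm must have equal length")
    short = d < threshold_mm
    return FCStrengthMaps(
        spfc=float(z[(z > 0) & short].sum()),
        lpfc=float(z[(z > 0) & ~short].sum()),
        snfc=float(z[(z < 0) & short].sum()),
        lnfc=float(z[(z < 0) & ~short].sum()),
        threshold_mm=threshold_mm,
    )


def strength_to_nifti(maps: FCStrengthMaps, grid: BrainGrid) -> dict:
    """Scatter the four strength vectors back into 3D NIfTI images."""
    import nibabel as nib

    out = {}
    for name, vec in maps.as_dict().items():
        vol = grid.vector_to_volume(np.asarray(vec, dtype=float).reshape(-1))
        out[name] = nib.Nifti1Image(vol.astype(np.float32), grid.affine)
    return out


def save_strength_maps(maps: FCStrengthMaps, grid: BrainGrid, out_dir,
                       include_negative: bool = False) -> list:
    """Write spfc/lpfc (optionally snfc/lnfc) NIfTIs for one subject."""
    import pathlib

    import nibabel as nib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = strength_to_nifti(maps, grid)
    names = ["spfc", "lpfc"] + (["snfc", "lnfc"] if include_negative else [])
    written = []
    for name in names:
        path = out_dir / f"{maps.subject_id or 'subject'}_{name}.nii.gz"
        nib.save(images[name], str(path))
        written.append(path)
    return written
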