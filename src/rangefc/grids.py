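"""Spatial containers: brain grids (masks + affines) and masked BOLD series.

A :class:`BrainGrid` fixes the voxel bookkeeping shared by every map in a
study: a 3D binary mask, a voxel-to-mm affine, and a deterministic ordering
of in-mask voxels (ascending C-order linear index).  All per-voxel vectors
(BOLD columns, FC-strength maps, t maps) use that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.affines import apply_affine


@dataclass
class BrainGrid:
    """Binary brain mask with an affine mapping voxel indices to mm space."""

    mask: np.ndarray
    affine: np.ndarray
    index_table: np.ndarray = field(init=False, repr=False)
    coords_mm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.affine.shape != (4, 4) or not np.isfinite(np.linalg.det(self.affine[:3, :3])):
            raise ValueError("affine must be an invertible 4x4 transform")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not self.mask.any():
            raise ValueError("mask is empty")
        # Deterministic in-mask ordering: ascending C-order linear index.
        self.index_table = np.flatnonzero(self.mask.ravel(order="C"))
        ijk = np.column_stack(np.unravel_index(self.index_table, self.mask.shape))
        self.coords_mm = apply_affine(self.affine, ijk)

    @property
    def voxel_count(self) -> int:
        return int(self.index_table.size)

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Physical voxel edge lengths along each axis (mm)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    # -- vector <-> volume -------------------------------------------------

    def vector_to_volume(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        vec = np.asarray(vec)
        if vec.shape != (self.voxel_count,):
            raise ValueError(f"expected length-{self.voxel_count} vector, got {vec.shape}")
        vol = np.full(self.mask.size, fill, dtype=float)
        vol[self.index_table] = vec
        return vol.reshape(self.mask.shape)

    def volume_to_vector(self, vol: np.ndarray) -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape != self.mask.shape:
            raise ValueError("volume shape does not match mask")
        return vol.ravel(order="C")[self.index_table].astype(float)

    # -- NIfTI io ----------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "BrainGrid":
        img = img_or_path if isinstance(img_or_path, nib.spatialimages.SpatialImage) else nib.load(str(img_or_path))
        return cls(mask=np.asanyarray(img.dataobj) > 0, affine=img.affine)


def load_mask_from_probability_map(prob_map, threshold: float = 0.2, affine=None) -> BrainGrid:
    """Threshold a tissue-probability map into a :class:`BrainGrid`.

    Voxels with probability strictly greater than ``threshold`` (default 0.2,
    the conventional gray-matter cutoff) enter the mask.
    """
    if isinstance(prob_map, (str,)) or hasattr(prob_map, "dataobj"):
        img = prob_map if hasattr(prob_map, "dataobj") else nib.load(str(prob_map))
        data = np.asanyarray(img.dataobj).astype(float)
        affine = img.affine
    else:
        data = np.asarray(prob_map, dtype=float)
        if affine is None:
            affine = np.eye(4)
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = data > threshold
    if not mask.any():
        raise ValueError("no voxel exceeds the probability threshold")
    return BrainGrid(mask=mask, affine=affine)


@dataclass
class BoldSeries:
    """One subject's masked BOLD data: T timepoints x V in-mask voxels."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x V matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_nifti(self, grid: BrainGrid) -> nib.Nifti1Image:
        vols = np.zeros(grid.mask.shape + (self.n_timepoints,), dtype=np.float32)
        flat = vols.reshape(-1, self.n_timepoints)
        flat[grid.index_table] = self.data.T
        img = nib.Nifti1Image(vols, grid.affine)
        img.header.set_zooms(tuple(grid.voxel_sizes_mm) + (self.tr_seconds,))
        return img

    def save(self, path, grid: BrainGrid) -> None:
        nib.save(self.to_nifti(grid), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, grid: BrainGrid, tr_seconds: float | None = None,
                   subject_id: str = "") -> "BoldSeries":
        img = img_or_path if hasattr(img_or_path, "dataobj") else nib.load(str(img_or_path))
        vols = np.asanyarray(img.dataobj)
        if vols.ndim != 4:
            raise ValueError("expected a 4D NIfTI series")
        if vols.shape[:3] != grid.mask.shape:
            raise ValueError("series grid does not match mask")
        if tr_seconds is None:
            tr_seconds = float(img.header.get_zooms()[3])
        data = vols.reshape(-1, vols.shape[3])[grid.index_table].T
        return cls(data=data, tr_seconds=tr_seconds, subject_id=subject_id)
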