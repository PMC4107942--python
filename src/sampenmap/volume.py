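"""4D fMRI volume and brain-mask containers with NIfTI-1 I/O.

A :class:`Volume4D` holds a ``(x, y, z, t)`` array of BOLD intensities together
with the voxel size (mm) and the repetition time TR (s); a :class:`BrainMask`
is a congruent 3D boolean grid of in-brain voxels.  File access goes through
nibabel; voxel size and TR are taken from the NIfTI header (``pixdim``) and may
be overridden by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume4D", "BrainMask", "load_volume", "save_volume", "load_mask", "save_mask"]


@dataclass
class Volume4D:
    """A 4D image: spatial grid ``(x, y, z)`` sampled at ``t`` time points."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D (x, y, z, t) array, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if min(self.data.shape[:3]) < 1:
            raise ValueError("spatial dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive reals")
        self.tr_seconds = float(self.tr_seconds)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """New volume with the same geometry but different data."""
        return Volume4D(data, self.voxel_size_mm, self.tr_seconds)


@dataclass
class BrainMask:
    """Boolean in-brain support congruent with a volume's spatial grid."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise ValueError("mask must be a 3D boolean grid")
        if not self.include.any():
            raise ValueError("mask is empty: at least one voxel must be included")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())

    def check_congruent(self, vol: Volume4D) -> None:
        if self.include.shape != vol.spatial_shape:
            raise ValueError(
                f"mask shape {self.include.shape} does not match volume grid {vol.spatial_shape}"
            )


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def save_volume(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.voxel_size_mm))
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume(path, tr_seconds: float | None = None,
                voxel_size_mm: tuple[float, float, float] | None = None) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        raise ValueError(f"{path} is a 3D image; a 4D time series is required")
    zooms = img.header.get_zooms()
    if voxel_size_mm is None:
        voxel_size_mm = tuple(float(z) for z in zooms[:3])
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Volume4D(data, voxel_size_mm, tr_seconds)


def save_mask(mask: BrainMask, path, voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)) -> None:
    img = nib.Nifti1Image(mask.include.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(np.asarray(img.get_fdata()) > 0.5)
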