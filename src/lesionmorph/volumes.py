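"""Volume carrier and shared image plumbing.

A :class:`Volume` is a 3-D scalar grid with a 4x4 voxel-to-world affine
(RAS+, 0-based voxel indices, voxel-centre convention).  It is the universal
carrier for structural images, tissue probability maps, binary masks and
statistic maps throughout the package.  NIfTI-1 reading/writing goes through
nibabel; smoothing and resampling through scipy.ndimage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "resample",
    "binarise",
    "fwhm_to_sigma",
]

#: conversion factor between Gaussian FWHM and standard deviation
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half maximum."""
    return float(fwhm) / FWHM_PER_SIGMA


@dataclass
class Volume:
    """3-D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values, stored as float unless the volume is a binary mask.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm map (voxel-centre convention, RAS+).
    space : str
        Either ``"native"`` (subject space) or ``"group"`` (template space).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or not np.all(np.isfinite(self.affine)):
            raise ValueError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel spacing per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid/affine/space but different data."""
        if np.asarray(data).shape != self.data.shape:
            raise ValueError("with_data requires identical shape")
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what} must share grid and affine")

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())


def read_volume(path) -> Volume:
    """Read a single-frame 3-D NIfTI-1 file.

    Raises a format error on 4-D inputs or non-finite affines.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError("NIfTI affine is missing or non-finite")
    return Volume(data=np.asarray(data, dtype=np.float32), affine=affine)


def write_volume(vol: Volume, path) -> None:
    """Write as NIfTI-1.  Binary masks are stored as uint8, else float32."""
    if vol.is_binary():
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with the kernel width given in mm FWHM.

    Edge handling uses a renormalised truncated kernel (smooth the image and
    an all-ones image with zero padding, then divide), which avoids mass
    leaking out of the field of view at the brain edge and leaves constant
    images unchanged.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vol.voxel_size_mm
    data = np.asarray(vol.data, dtype=float)
    num = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(
        np.ones_like(data), sigma=sigma_vox, mode="constant", cval=0.0
    )
    return vol.with_data(num / den)


def resample(
    vol: Volume,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    order: int = 1,
) -> Volume:
    """Resample onto a target grid by sampling at target voxel centres.

    Values are interpolated with a b-spline of the requested ``order``
    (0..4); voxels mapping outside the source field of view are 0.
    """
    if order not in (0, 1, 2, 3, 4):
        raise ValueError("interpolation order must be in 0..4")
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValueError("target affine is singular")
    # voxel(target) -> world -> voxel(source)
    M = np.linalg.inv(vol.affine) @ target_affine
    ii, jj, kk = np.meshgrid(
        np.arange(target_shape[0]),
        np.arange(target_shape[1]),
        np.arange(target_shape[2]),
        indexing="ij",
    )
    coords = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (M @ coords)[:3]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), src, order=order, mode="constant", cval=0.0
    ).reshape(target_shape)
    return Volume(data=out, affine=target_affine, space=vol.space)


def binarise(prob: Volume, threshold: float) -> Volume:
    """Threshold a probability map: data >= threshold -> 1 else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return prob.with_data((np.asarray(prob.data) >= threshold).astype(np.uint8))
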