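"""Gray-matter volume I/O, geometry, Gaussian smoothing and the analysis mask.

Volumes are spatially normalized, modulated gray-matter density maps in a
common (MNI) space: a 3D array of unitless tissue density plus a 4x4
voxel-index -> MNI-mm affine.  Data are stored float32 on disk (NIfTI
convention) and promoted to float64 for computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Kernel support used for smoothing, in units of sigma.  Truncating at
#: 3*sigma makes the convolution exactly mass-preserving for any image whose
#: nonzero content keeps a >= 3*sigma zero margin from the array boundary.
KERNEL_TRUNCATE_SD = 3.0


@dataclass(frozen=True)
class GMVolume:
    """One subject's gray-matter density map with its voxel->MNI affine.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Modulated GM density; finite and non-negative.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> MNI-mm transform; must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        affine = np.asarray(self.affine, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {data.ndim}D")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains NaN or infinite voxels")
        if np.any(data < 0):
            raise ValueError("GM density must be non-negative")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge length per axis in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return abs(np.linalg.det(self.affine[:3, :3])) / 1000.0

    def same_geometry(self, other: "GMVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


def read_volume(path) -> GMVolume:
    """Load a 3D NIfTI-1 gray-matter map.

    Raises on non-3D images, NaN voxels, or a singular affine.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return GMVolume(data=data, affine=np.asarray(img.affine, dtype=np.float64))


def write_volume(vol: GMVolume, path) -> None:
    """Write a volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def write_stat_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write an arbitrary (possibly signed) statistic map as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    return fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size, dtype=np.float64)


def smooth_volume(vol: GMVolume, fwhm_mm: float) -> GMVolume:
    """Gaussian-smooth a volume with a kernel of the given FWHM in mm.

    The kernel is isotropic in mm: anisotropic voxel sizes get a per-axis
    sigma of ``fwhm / (voxel_size * 2*sqrt(2 ln 2))`` voxels.  Boundaries
    are zero-padded; with the kernel truncated at 3 sigma the total voxel
    sum is exactly preserved whenever the image content keeps a 3-sigma
    zero margin.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol
    sigma = _fwhm_to_sigma_vox(fwhm_mm, vol.voxel_size)
    out = ndimage.gaussian_filter(
        vol.data, sigma=sigma, mode="constant", cval=0.0, truncate=KERNEL_TRUNCATE_SD
    )
    # float roundoff can leave tiny negatives on a non-negative input
    np.clip(out, 0.0, None, out=out)
    return GMVolume(data=out, affine=vol.affine)


def smooth_array(data: np.ndarray, voxel_size, fwhm_mm: float) -> np.ndarray:
    """Smoothing kernel applied to a bare array (no non-negativity clamp)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(data, dtype=np.float64)
    sigma = _fwhm_to_sigma_vox(fwhm_mm, np.asarray(voxel_size, dtype=np.float64))
    return ndimage.gaussian_filter(
        np.asarray(data, dtype=np.float64),
        sigma=sigma,
        mode="constant",
        cval=0.0,
        truncate=KERNEL_TRUNCATE_SD,
    )


def analysis_mask(cohort, threshold: float = 0.1) -> np.ndarray:
    """Boolean analysis mask: voxels whose mean GM density across subjects
    is at or above ``threshold``.

    The mask restricts every voxel-wise fit and the FDR correction to
    brain tissue; 0.1 is the conventional absolute-density cutoff for
    modulated GM maps.
    """
    if cohort.n_subjects == 0:
        raise ValueError("cannot build a mask from an empty cohort")
    mean = cohort.data.mean(axis=0)
    return mean >= threshold
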