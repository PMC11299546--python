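"""Volume container, NIfTI I/O, isotropic resampling and FWHM smoothing.

All images in the package travel as :class:`Volume` objects: a 3-D scalar
array plus a 4x4 voxel-to-world affine (RAS, millimetres).  Voxel indices are
0-based; interpolation is trilinear by default and nearest-neighbour for
label volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = SIG2FWHM * sigma
SIG2FWHM = float(np.sqrt(8.0 * np.log(2.0)))


class FormatError(ValueError):
    """Raised when a file cannot be parsed as NIfTI-1."""


@dataclass
class Volume:
    """3-D scalar grid with world geometry.

    Parameters
    ----------
    data:
        3-D array of scalars (any numeric dtype; promoted to float32 on write
        if the dtype cannot be stored natively).
    affine:
        4x4 voxel-to-world matrix mapping 0-based voxel indices to RAS mm.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(self.data.copy() if data is None else np.asarray(data),
                      self.affine.copy())

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume on this grid holding ``data``."""
        if np.shape(data) != self.shape:
            raise ValueError("data shape does not match grid")
        return Volume(np.asarray(data), self.affine.copy())


def read_volume(path) -> Volume:
    """Read a NIfTI-1 image as a :class:`Volume`.

    Raises
    ------
    FormatError
        If the file is not a valid NIfTI image.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"not a readable NIfTI image: {path} ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected 3-D image, got shape {data.shape}: {path}")
    return Volume(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(vol: Volume, path, dtype=None) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz).

    Integer arrays are stored as-is; float data is stored as float32 unless
    ``dtype`` overrides it (float64 inputs are promoted down with a log note).
    """
    data = vol.data
    if dtype is None:
        if np.issubdtype(data.dtype, np.integer):
            dtype = data.dtype
        else:
            if data.dtype != np.float32:
                log.info("storing %s data as float32", data.dtype)
            dtype = np.float32
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), vol.affine)
    nib.save(img, str(path))


def _displacement_to_4d(disp: np.ndarray) -> np.ndarray:
    if disp.ndim != 4 or disp.shape[-1] != 3:
        raise ValueError("displacement must have shape (nx, ny, nz, 3)")
    return disp


def write_displacement(disp: np.ndarray, affine: np.ndarray, path) -> None:
    """Store a dense displacement field (mm, world frame) as a 4-D NIfTI."""
    img = nib.Nifti1Image(np.asarray(_displacement_to_4d(disp), dtype=np.float32),
                          np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def read_displacement(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return _displacement_to_4d(data), np.asarray(img.affine)


def resample_isotropic(vol: Volume, target_mm: float = 1.0,
                       order: int = 1) -> Volume:
    """Resample to an isotropic grid of ``target_mm`` voxels.

    World-space extent is preserved within one target voxel; interpolation is
    trilinear (``order=1``) by default, ``order=0`` for label volumes.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    vs = vol.voxel_size
    if np.allclose(vs, target_mm, atol=1e-9):
        return vol.copy()
    new_shape = np.maximum(1, np.ceil(np.asarray(vol.shape) * vs / target_mm)
                           ).astype(int)
    # new affine: same origin and axis directions, rescaled voxel step
    scale = target_mm / vs
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] * scale[np.newaxis, :]
    # map new voxel indices into old voxel coordinates
    inv_old = np.linalg.inv(vol.affine)
    comb = inv_old @ new_affine
    grid = np.indices(tuple(new_shape), dtype=np.float64)
    coords = np.einsum("ab,b...->a...", comb[:3, :3],
                       grid) + comb[:3, 3][:, None, None, None]
    data = ndimage.map_coordinates(np.asarray(vol.data, dtype=np.float64),
                                   coords, order=order, mode="constant", cval=0.0)
    return Volume(data, new_affine)


def smooth_fwhm(vol: Volume, fwhm_mm: float) -> Volume:
    """Gaussian smoothing with the kernel width given as FWHM in mm.

    ``fwhm_mm=0`` is the identity.  Plain zero-padded convolution; the
    volume integral is conserved for supports well inside the grid.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = (fwhm_mm / SIG2FWHM) / vol.voxel_size
    data = ndimage.gaussian_filter(np.asarray(vol.data, dtype=np.float64),
                                   sigma=sigma_vox, mode="constant", cval=0.0)
    return vol.like(data)
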