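"""Diffeomorphic image registration and Jacobian modulation.

A desk-scale stand-in for large-deformation template registration: a
stationary-velocity-field demons optimizer whose velocity is Gaussian
regularized and exponentiated by scaling-and-squaring, so the resulting
mapping is diffeomorphic (positive Jacobian) by construction.  Fields warp
tissue maps into a common frame; multiplying the warped map by the Jacobian
determinant (modulation) preserves each subject's regional tissue volume,
which is what voxel-based morphometry analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Volume

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Raised when the images cannot be brought into register."""


@dataclass
class DeformationField:
    """Dense displacement field on a reference grid.

    ``displacement[i, j, k]`` is the 3-vector (mm, world frame) added to the
    world position of voxel (i, j, k) to obtain the pull-back sampling
    location: warping evaluates ``moving(x + u(x))`` on the fixed grid.
    """

    displacement: np.ndarray          # (nx, ny, nz, 3) mm
    grid: Volume                      # carries shape + affine of the reference
    _jacobian: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.shape != self.grid.shape + (3,):
            raise ValueError("displacement shape does not match grid")

    @classmethod
    def identity(cls, grid: Volume) -> "DeformationField":
        return cls(np.zeros(grid.shape + (3,)), grid)

    @property
    def jacobian(self) -> Volume:
        if self._jacobian is None:
            self._jacobian = _jacobian_det(self.displacement, self.grid)
        return self.grid.like(self._jacobian)


def _mm_to_voxel_disp(disp_mm: np.ndarray, grid: Volume) -> np.ndarray:
    inv = np.linalg.inv(grid.affine[:3, :3])
    return np.einsum("ab,...b->...a", inv, disp_mm)


def _voxel_to_mm_disp(disp_vox: np.ndarray, grid: Volume) -> np.ndarray:
    return np.einsum("ab,...b->...a", grid.affine[:3, :3], disp_vox)


def _sample_displacement(disp_vox: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    out = np.empty_like(disp_vox)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            disp_vox[..., c], coords_vox, order=1, mode="nearest")
    return out


def exp_velocity(vel_vox: np.ndarray, n_steps: int | None = None) -> np.ndarray:
    """Exponentiate a stationary velocity (voxel units) by scaling-and-squaring.

    Returns the displacement of exp(v).  ``n_steps`` defaults to the smallest
    count making the scaled step < 0.4 voxel, which keeps every squaring
    composition well inside the diffeomorphic regime.
    """
    vmax = float(np.max(np.linalg.norm(vel_vox, axis=-1))) if vel_vox.size else 0.0
    if n_steps is None:
        n_steps = max(0, int(np.ceil(np.log2(max(vmax, 1e-12) / 0.4))))
        n_steps = min(n_steps, 16)
    u = vel_vox / (2.0 ** n_steps)
    grid = np.indices(u.shape[:3], dtype=np.float64)
    for _ in range(n_steps):
        coords = grid + np.moveaxis(u, -1, 0)
        u = u + _sample_displacement(u, coords)
    return u


def _jacobian_det(disp_mm: np.ndarray, grid: Volume) -> np.ndarray:
    """Determinant of the spatial gradient of x -> x + u(x), world frame."""
    vs = grid.voxel_size
    J = np.zeros(disp_mm.shape[:3] + (3, 3))
    for comp in range(3):
        for axis in range(3):
            J[..., comp, axis] = np.gradient(disp_mm[..., comp],
                                             vs[axis], axis=axis)
    # direction cosines: voxel axes may not align with world axes
    dircos = grid.affine[:3, :3] / vs[np.newaxis, :]
    J = np.einsum("...ca,ab->...cb", J, np.linalg.inv(dircos))
    J += np.eye(3)
    return np.linalg.det(J)


def jacobian_det(fld: DeformationField) -> Volume:
    """Jacobian-determinant map of a deformation (local volume change)."""
    return fld.jacobian


def warp(vol: Volume, fld: DeformationField, interp: str = "linear") -> Volume:
    """Pull a moving image back through a deformation onto the fixed grid.

    ``interp`` is "linear" for scalar maps or "nearest" for label volumes;
    trilinear interpolation of integer labels is refused.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError("interp must be 'linear' or 'nearest'")
    is_label = np.issubdtype(vol.data.dtype, np.integer)
    if is_label and interp != "nearest":
        raise ValueError("label volumes must be warped with interp='nearest'")
    grid = fld.grid
    ijk = np.indices(grid.shape, dtype=np.float64)
    world = (np.einsum("ab,b...->a...", grid.affine[:3, :3], ijk)
             + grid.affine[:3, 3][:, None, None, None])
    world = world + np.moveaxis(fld.displacement, -1, 0)
    inv = np.linalg.inv(vol.affine)
    coords = (np.einsum("ab,b...->a...", inv[:3, :3], world)
              + inv[:3, 3][:, None, None, None])
    order = 0 if interp == "nearest" else 1
    data = ndimage.map_coordinates(np.asarray(vol.data, dtype=np.float64),
                                   coords, order=order, mode="constant", cval=0.0)
    if is_label:
        data = np.asarray(np.rint(data), dtype=vol.data.dtype)
    return Volume(data, grid.affine.copy())


def modulate(warped: Volume, jacobian: Volume) -> Volume:
    """Multiply a warped tissue map by the Jacobian determinant.

    After modulation the integral of a tissue map over template space equals
    the subject's native-space tissue volume.
    """
    if warped.shape != jacobian.shape:
        raise ValueError("grids do not match")
    return warped.like(warped.data * jacobian.data)


def _moments_affine(fixed: Volume, moving: Volume) -> np.ndarray:
    """Rigid+isotropic-scale pre-alignment from image moments (world frame).

    Returns a 4x4 matrix A such that moving is sampled at A @ x_fixed.
    Deterministic; rotation omitted (principal axes of near-spherical
    phantoms are ill-conditioned, translation+scale suffices).
    """
    def com_and_spread(v: Volume):
        w = np.clip(np.asarray(v.data, dtype=np.float64), 0, None)
        tot = w.sum()
        if tot <= 0:
            raise RegistrationError("image has no positive mass")
        ijk = np.indices(v.shape, dtype=np.float64)
        com_vox = np.array([(ijk[a] * w).sum() / tot for a in range(3)])
        com = v.voxel_to_world(com_vox)[0]
        world = (np.einsum("ab,b...->a...", v.affine[:3, :3], ijk)
                 + v.affine[:3, 3][:, None, None, None])
        d2 = sum((world[a] - com[a]) ** 2 for a in range(3))
        spread = np.sqrt((d2 * w).sum() / tot)
        return com, spread

    com_f, sp_f = com_and_spread(fixed)
    com_m, sp_m = com_and_spread(moving)
    s = sp_m / sp_f
    A = np.eye(4)
    A[:3, :3] *= s
    A[:3, 3] = com_m - s * com_f
    return A


def _demons_force(fixed: np.ndarray, warped: np.ndarray,
                  vs: np.ndarray) -> np.ndarray:
    """Symmetric-gradient demons update (voxel displacement units)."""
    diff = fixed - warped
    gf = np.stack(np.gradient(fixed, *vs), axis=-1)
    gw = np.stack(np.gradient(warped, *vs), axis=-1)
    g = 0.5 * (gf + gw)
    g2 = np.sum(g * g, axis=-1)
    scale = np.mean(np.abs(diff)) + 1e-12
    denom = g2 + (diff / scale) ** 2 * 1e-2 + 1e-9
    upd = (diff / denom)[..., None] * g
    # cap the update to half a voxel for stability
    mag = np.linalg.norm(upd, axis=-1, keepdims=True)
    upd = np.where(mag > 0.5, upd * (0.5 / (mag + 1e-12)), upd)
    return upd


def register_diffeo(fixed: Volume, moving: Volume, levels: int = 3,
                    iters_per_level: int = 30, smooth_mm: float = 6.0,
                    diffusion_mm: float = 1.0,
                    seed: int | None = None,
                    pre_align: bool = True) -> DeformationField:
    """Diffeomorphic registration of ``moving`` onto ``fixed``.

    Multi-resolution stationary-velocity demons: at each pyramid level a
    demons-style force is fluid-regularized with ``smooth_mm``, added to
    the velocity, which is then diffusion-regularized with ``diffusion_mm``
    and exponentiated by scaling-and-squaring to produce the current
    diffeomorphism.  Deterministic given its inputs (``seed`` is accepted
    for interface symmetry; no randomness is used).

    Returns the forward field on the fixed grid, whose ``jacobian`` is
    guaranteed positive.
    """
    del seed
    A = _moments_affine(fixed, moving) if pre_align else np.eye(4)

    fdat = np.asarray(fixed.data, dtype=np.float64)
    # moving resampled through the affine onto the fixed grid once per level
    scale = max(np.ptp(fdat), 1e-12)

    vel = None  # voxel units on the current level grid
    shapes = []
    for lev in range(levels - 1, -1, -1):
        factor = 2 ** lev
        shp = tuple(max(4, int(np.ceil(s / factor))) for s in fixed.shape)
        shapes.append((lev, factor, shp))

    for lev, factor, shp in shapes:
        zoom = np.asarray(shp) / np.asarray(fixed.shape)
        aff_l = fixed.affine.copy()
        aff_l[:3, :3] = fixed.affine[:3, :3] / zoom[np.newaxis, :]
        vs_l = np.linalg.norm(aff_l[:3, :3], axis=0)

        ijk = np.indices(shp, dtype=np.float64)
        world = (np.einsum("ab,b...->a...", aff_l[:3, :3], ijk)
                 + aff_l[:3, 3][:, None, None, None])
        # sample fixed on the level grid through the same world-coordinate
        # path used for the moving image, so identical inputs give zero force
        inv_fix = np.linalg.inv(fixed.affine)
        fix_coords = (np.einsum("ab,b...->a...", inv_fix[:3, :3], world)
                      + inv_fix[:3, 3][:, None, None, None])
        f_l = ndimage.map_coordinates(fdat, fix_coords, order=1,
                                      mode="constant", cval=0.0)

        if vel is None:
            vel = np.zeros(shp + (3,))
        else:
            zf = np.asarray(shp) / np.asarray(vel.shape[:3])
            vel = np.stack([ndimage.zoom(vel[..., c] * zf[c], zf, order=1,
                                         mode="nearest") for c in range(3)],
                           axis=-1)

        sigma_fluid = (smooth_mm / vs_l) / np.sqrt(8 * np.log(2))
        sigma_diff = (diffusion_mm / vs_l) / np.sqrt(8 * np.log(2))
        inv_mov = np.linalg.inv(moving.affine)
        mdat = np.asarray(moving.data, dtype=np.float64)

        def _warp_moving(disp_vox):
            wrl = world + np.moveaxis(
                np.einsum("ab,...b->...a", aff_l[:3, :3], disp_vox), -1, 0)
            wrl_aff = np.einsum("ab,b...->a...", A[:3, :3], wrl) \
                + A[:3, 3][:, None, None, None]
            coords = (np.einsum("ab,b...->a...", inv_mov[:3, :3], wrl_aff)
                      + inv_mov[:3, 3][:, None, None, None])
            return ndimage.map_coordinates(mdat, coords, order=1,
                                           mode="constant", cval=0.0)

        prev_sse = np.inf
        for _ in range(iters_per_level):
            disp = exp_velocity(vel)
            w = _warp_moving(disp)
            sse = float(np.mean((f_l - w) ** 2))
            if sse > prev_sse * 0.9999:
                break
            prev_sse = sse
            upd = _demons_force(f_l / scale, w / scale, vs_l)
            for c in range(3):
                upd[..., c] = ndimage.gaussian_filter(
                    upd[..., c], sigma_fluid[c], mode="nearest")
            vel = vel + upd
            if diffusion_mm > 0:
                for c in range(3):
                    vel[..., c] = ndimage.gaussian_filter(
                        vel[..., c], sigma_diff[c], mode="nearest")

    disp_vox = exp_velocity(vel)
    # full-resolution displacement, composed with the affine pre-alignment:
    # total world mapping x -> A @ (x + u(x)); store as displacement
    if vel.shape[:3] != fixed.shape:
        zf = np.asarray(fixed.shape) / np.asarray(disp_vox.shape[:3])
        disp_vox = np.stack([ndimage.zoom(disp_vox[..., c] * zf[c], zf, order=1,
                                          mode="nearest") for c in range(3)],
                            axis=-1)
    ijk = np.indices(fixed.shape, dtype=np.float64)
    world = (np.einsum("ab,b...->a...", fixed.affine[:3, :3], ijk)
             + fixed.affine[:3, 3][:, None, None, None])
    world = np.moveaxis(world, 0, -1)
    disp_mm = np.einsum("ab,...b->...a", fixed.affine[:3, :3], disp_vox)
    mapped = np.einsum("ab,...b->...a", A[:3, :3], world + disp_mm) + A[:3, 3]
    field = DeformationField(mapped - world, fixed)
    jmin = float(field.jacobian.data.min())
    if jmin <= 0:
        raise RegistrationError(f"non-positive Jacobian ({jmin:.3g}) — "
                                "registration left the diffeomorphic regime")
    # overlap sanity check
    w = warp(moving, field)
    if float(np.abs(w.data).sum()) == 0.0 and float(np.abs(moving.data).sum()) > 0:
        raise RegistrationError("no overlap between images after alignment")
    return field


def build_template(volumes: list[Volume], n_iter: int = 3,
                   return_history: bool = False, **reg_kwargs):
    """Iterative unbiased mean image of a cohort.

    Registers every volume to the current mean, averages the warped images,
    and repeats; the template sharpens as anatomy comes into register.
    With ``return_history=True`` also returns the template after each
    iteration (starting from the naive mean).
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    ref = volumes[0]
    stack = []
    for v in volumes:
        if v.shape != ref.shape:
            raise ValueError("all volumes must share a grid")
        stack.append(np.asarray(v.data, dtype=np.float64))
    template = ref.like(np.mean(stack, axis=0))
    history = [template]
    for _ in range(n_iter):
        warped = [warp(v, register_diffeo(template, v, **reg_kwargs)).data
                  for v in volumes]
        template = ref.like(np.mean(warped, axis=0))
        history.append(template)
    if return_history:
        return template, history
    return template
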