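"""Synthetic brain phantoms with exact tissue ground truth.

The phantom emulates simulated-MRI ground-truth resources: a star-shaped
"cortex" built from a white-matter ball whose radius is perturbed by a
smooth angular folding term, wrapped in a gray-matter shell of constant
normal thickness and an outer CSF shell.  Tissue fractions are computed by
supersampling, so partial-volume effects at tissue interfaces are realistic,
while the generating parameters (true thickness, tissue means, noise sigma,
total intracranial volume) stay exactly known.

Noise follows the simulated-MRI convention: ``noise_percent`` is the
Gaussian sigma expressed as a percentage of the white-matter mean intensity.
The bias field is the lowest-order separable polynomial (a linear ramp)
scaled to the requested peak-to-peak percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .volume_io import Volume
from .register import DeformationField, exp_velocity

SUPERSAMPLE = 3  # per-axis subdivision for fraction computation

LABEL_BG, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3


class SizingError(ValueError):
    """Phantom geometry does not fit the requested grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of a phantom; a pure function of these fields.

    Attributes
    ----------
    grid_shape : voxels per axis.
    voxel_size : isotropic voxel edge in mm.
    wm_radius : mean radius of the white-matter core in mm.
    gm_thickness : normal thickness of the gray-matter shell in mm.
    csf_thickness : thickness of the surrounding CSF shell in mm.
    fold_amplitude : amplitude in mm of the angular folding perturbation.
    fold_frequency : integer number of folds per revolution.
    intensity_means : (CSF, GM, WM) image intensities, strictly increasing
        (T1-weighted ordering).
    noise_percent : Gaussian noise sigma as % of the WM mean.
    bias_percent : peak-to-peak multiplicative bias in %.
    seed : RNG seed; identical specs produce bit-identical phantoms.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 1.0
    wm_radius: float = 10.0
    gm_thickness: float = 4.0
    csf_thickness: float = 3.0
    fold_amplitude: float = 0.0
    fold_frequency: int = 4
    intensity_means: tuple[float, float, float] = (40.0, 80.0, 120.0)
    noise_percent: float = 0.0
    bias_percent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        c, g, w = self.intensity_means
        if not (c < g < w):
            raise ValueError("intensity_means must be strictly increasing "
                             "(CSF < GM < WM)")
        if self.noise_percent < 0:
            raise ValueError("noise_percent must be >= 0")
        if self.gm_thickness <= 0:
            raise ValueError("gm_thickness must be > 0")
        if self.bias_percent < 0:
            raise ValueError("bias_percent must be >= 0")
        extent = (self.wm_radius + self.gm_thickness + self.csf_thickness
                  + self.fold_amplitude + 4 * self.voxel_size)
        half = min(self.grid_shape) * self.voxel_size / 2.0
        if extent > half:
            raise SizingError(
                f"geometry radius {extent:.1f} mm exceeds half-grid "
                f"{half:.1f} mm; enlarge grid_shape or shrink the phantom")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom."""

    hard_labels: Volume                 # 0 BG, 1 CSF, 2 GM, 3 WM
    fractions: dict[str, Volume]        # keys csf/gm/wm, sum to 1 in head
    true_thickness_mm: float
    thickness_map: Volume               # constant thickness on GM voxels
    tiv_ml: float
    spec: PhantomSpec
    noiseless: Volume = field(default=None)  # bias-free, noise-free image


def _subsample_radii(spec: PhantomSpec):
    """Subvoxel-center coordinates (mm, origin at grid center) and radii."""
    n = SUPERSAMPLE
    shape = np.asarray(spec.grid_shape)
    fine = shape * n
    h = spec.voxel_size / n
    axes = [(np.arange(fine[a]) + 0.5) * h - shape[a] * spec.voxel_size / 2.0
            for a in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True), h


def _wm_mask_fine(spec: PhantomSpec, coords):
    x, y, z = coords
    r = np.sqrt(x * x + y * y + z * z)
    if spec.fold_amplitude == 0.0:
        return r <= spec.wm_radius, r
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.divide(z, np.maximum(r, 1e-12)), -1, 1))
    phi = np.arctan2(y, x)
    R = spec.wm_radius + spec.fold_amplitude * \
        np.sin(spec.fold_frequency * theta) * np.sin(spec.fold_frequency * phi)
    return r <= R, r


def _fractions_from_fine(cls_fine: np.ndarray, shape) -> dict[str, np.ndarray]:
    n = SUPERSAMPLE
    out = {}
    view = cls_fine.reshape(shape[0], n, shape[1], n, shape[2], n)
    for name, code in (("csf", LABEL_CSF), ("gm", LABEL_GM), ("wm", LABEL_WM)):
        out[name] = (view == code).mean(axis=(1, 3, 5))
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate a phantom image and its exact ground truth.

    The white-matter core is the region ``r <= wm_radius + fold_amplitude *
    sin(f*theta)*sin(f*phi)``; gray matter is the set of points within
    ``gm_thickness`` (Euclidean distance) of the core, giving a shell of
    constant normal thickness; CSF fills the next ``csf_thickness`` mm.
    Fractions come from 3x3x3 supersampling of every voxel; the image is the
    fraction-weighted mixture of the class means, multiplied by the bias
    field and corrupted with seeded Gaussian noise.
    """
    shape = spec.grid_shape
    coords, h = _subsample_radii(spec)
    wm_fine, r = _wm_mask_fine(spec, coords)

    if spec.fold_amplitude == 0.0:
        dist = np.maximum(r - spec.wm_radius, 0.0)
    else:
        # Euclidean distance to the folded core, half-sample corrected so a
        # flat interface midway between sample centers reads distance zero.
        dist = ndimage.distance_transform_edt(~wm_fine, sampling=h)
        dist = np.maximum(dist - 0.5 * h, 0.0)
        dist[wm_fine] = 0.0

    cls_fine = np.zeros(wm_fine.shape, dtype=np.uint8)
    cls_fine[wm_fine] = LABEL_WM
    gm_fine = (~wm_fine) & (dist <= spec.gm_thickness)
    cls_fine[gm_fine] = LABEL_GM
    csf_fine = (~wm_fine) & (~gm_fine) & \
        (dist <= spec.gm_thickness + spec.csf_thickness)
    cls_fine[csf_fine] = LABEL_CSF

    fracs = _fractions_from_fine(cls_fine, shape)
    frac_sum = fracs["csf"] + fracs["gm"] + fracs["wm"]

    # voxel center i sits at (i + 0.5) * h - L/2: grid centered on the origin
    affine = np.eye(4)
    affine[:3, :3] *= spec.voxel_size
    affine[:3, 3] = (0.5 - np.asarray(shape) / 2.0) * spec.voxel_size

    m_csf, m_gm, m_wm = spec.intensity_means
    clean = (fracs["csf"] * m_csf + fracs["gm"] * m_gm + fracs["wm"] * m_wm)

    img = clean.copy()
    if spec.bias_percent > 0:
        xi = np.linspace(-1.0, 1.0, shape[0])[:, None, None]
        img = img * (1.0 + (spec.bias_percent / 200.0) * xi)
    if spec.noise_percent > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_percent / 100.0 * m_wm
        img = img + rng.normal(0.0, sigma, size=shape)

    stacked = np.stack([fracs["csf"], fracs["gm"], fracs["wm"]])
    bg = np.clip(1.0 - frac_sum, 0.0, 1.0)
    hard = np.where(bg >= stacked.max(axis=0), LABEL_BG,
                    np.argmax(stacked, axis=0) + 1).astype(np.int16)

    vol = Volume(img, affine)
    thick_map = np.where(hard == LABEL_GM, spec.gm_thickness, 0.0)
    tiv_ml = float((frac_sum > 0.5).sum()) * spec.voxel_size ** 3 / 1000.0
    truth = PhantomTruth(
        hard_labels=Volume(hard, affine.copy()),
        fractions={k: Volume(v, affine.copy()) for k, v in fracs.items()},
        true_thickness_mm=spec.gm_thickness,
        thickness_map=Volume(thick_map, affine.copy()),
        tiv_ml=tiv_ml,
        spec=spec,
        noiseless=Volume(clean, affine.copy()),
    )
    return vol, truth


def generate_cohort(n_per_group: int, atrophy_percent: float,
                    base_spec: PhantomSpec, seed: int = 0,
                    jitter: float = 0.02):
    """Two-group cohort with a planted gray-matter atrophy effect.

    Group "A" phantoms follow ``base_spec``; group "B" phantoms have
    ``gm_thickness`` reduced by ``atrophy_percent``.  Every subject receives
    seeded jitter (default 2% s.d.) on ``wm_radius`` and on the intensity
    means, emulating anatomical and scanner variability.

    Returns a list of ``(Volume, PhantomTruth, group_label, tiv_ml)``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not (0 <= atrophy_percent < 100):
        raise ValueError("atrophy_percent must be in [0, 100)")
    rng = np.random.default_rng(seed)
    out = []
    for group in ("A", "B"):
        thick = base_spec.gm_thickness
        if group == "B":
            thick *= (1.0 - atrophy_percent / 100.0)
        for _ in range(n_per_group):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            jr = 1.0 + (jitter * rng.standard_normal() if jitter else 0.0)
            ji = 1.0 + (jitter * rng.standard_normal() if jitter else 0.0)
            spec = replace(
                base_spec,
                gm_thickness=thick,
                wm_radius=base_spec.wm_radius * jr,
                intensity_means=tuple(m * ji for m in base_spec.intensity_means),
                seed=sub_seed,
            )
            vol, truth = generate_phantom(spec)
            out.append((vol, truth, group, truth.tiv_ml))
    return out


def generate_deformation(grid_shape, amplitude_mm: float, smoothness_mm: float,
                         seed: int = 0, voxel_size: float = 1.0
                         ) -> DeformationField:
    """Smooth invertible random deformation with known statistics.

    A Gaussian-filtered random velocity field is rescaled so its maximum
    magnitude is ``amplitude_mm`` (clipped if needed to keep the Jacobian
    positive) and exponentiated by scaling-and-squaring, which makes the
    result a diffeomorphism by construction.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    shape = tuple(int(s) for s in grid_shape)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = (0.5 - np.asarray(shape) / 2.0) * voxel_size
    grid = Volume(np.zeros(shape), affine)
    if amplitude_mm == 0:
        return DeformationField.identity(grid)
    rng = np.random.default_rng(seed)
    vel = rng.standard_normal(shape + (3,))
    sigma_vox = smoothness_mm / voxel_size
    for c in range(3):
        vel[..., c] = ndimage.gaussian_filter(vel[..., c], sigma_vox,
                                              mode="constant")
    mag = np.linalg.norm(vel, axis=-1)
    vel *= (amplitude_mm / voxel_size) / max(mag.max(), 1e-12)
    disp_vox = exp_velocity(vel)
    disp_mm = disp_vox * voxel_size
    fld = DeformationField(disp_mm, grid)
    jmin = float(fld.jacobian.data.min())
    if jmin <= 0:  # pragma: no cover - construction should prevent this
        raise RuntimeError(f"deformation lost invertibility (min J {jmin:.3g})")
    return fld
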