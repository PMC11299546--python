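"""Adaptive MAP tissue segmentation with partial-volume estimation.

Classifies a T1-weighted image into CSF / GM / WM without atlas priors: a
k-means start provides spatially constant class means, which an iterated
EM/ICM loop then refines into *locally varying* mean fields (class-weighted
intensities smoothed with a wide Gaussian), making the classifier robust to
smooth intensity inhomogeneity.  A Potts Markov-random-field prior
regularizes the labeling, and a 5-class partial-volume step resolves mixed
CSF/GM and GM/WM voxels into continuous tissue fractions on the 1-3 label
scale (1 = CSF, 2 = GM, 3 = WM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import SIG2FWHM, Volume

log = logging.getLogger(__name__)

TISSUES = ("csf", "gm", "wm")


class DegenerateInputError(ValueError):
    """Input has too little intensity structure to segment."""


class UndefinedKappaError(ZeroDivisionError):
    """Kappa is undefined because chance agreement is 1."""


@dataclass
class TissueModel:
    """Per-tissue intensity model with locally varying means."""

    mean_fields: dict[str, Volume]   # CSF/GM/WM local mean images
    variances: dict[str, float]
    mrf_beta: float = 0.1

    def local_means(self) -> np.ndarray:
        """Stack (3, nx, ny, nz) in CSF, GM, WM order."""
        return np.stack([self.mean_fields[t].data for t in TISSUES])


@dataclass
class PveSegmentation:
    """Probability maps, continuous PVE labels and the fitted tissue model.

    ``head_fraction`` is the estimated intracranial fraction of each voxel:
    1 inside the head, fractional on mask-boundary voxels whose intensity
    sits below the local CSF mean (partial background).  Volume summaries
    weight the probabilities with it so boundary voxels count fractionally.
    """

    prob: dict[str, Volume]
    pve_label: Volume
    gm_fraction: Volume
    model: TissueModel
    mask: np.ndarray
    n_iter: int = 0
    head_fraction: np.ndarray | None = None

    def hard_labels(self) -> Volume:
        """0 background, 1 CSF, 2 GM, 3 WM by maximum probability."""
        stacked = np.stack([self.prob[t].data for t in TISSUES])
        hard = (np.argmax(stacked, axis=0) + 1).astype(np.int16)
        hard[~self.mask] = 0
        return self.pve_label.like(hard)


def head_mask(vol: Volume, closing_mm: float = 2.0) -> np.ndarray:
    """Foreground mask by Otsu threshold + closing + hole filling."""
    from skimage.filters import threshold_otsu

    data = ndimage.gaussian_filter(np.asarray(vol.data, dtype=np.float64), 1.0)
    thr = threshold_otsu(data)
    # Otsu on a 3-tissue histogram can land between GM and WM; take a
    # generous fraction of it so CSF stays inside the head mask.
    mask = data > 0.35 * thr
    it = max(1, int(round(closing_mm / float(np.mean(vol.voxel_size)))))
    mask = ndimage.binary_closing(mask, iterations=it)
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def init_classes(vol: Volume, mask: np.ndarray, mrf_beta: float = 0.1,
                 max_iter: int = 50) -> TissueModel:
    """Deterministic 3-class k-means on masked intensities.

    Centers start at the 25/50/75% quantiles (no random initialization).
    After convergence each center is refined to the histogram mode of its
    class, which lands on the pure-tissue intensity rather than the
    partial-volume-shifted cluster mean.  Means are returned sorted
    ascending, broadcast as spatially constant mean fields for the
    adaptive MAP loop.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1000:
        raise ValueError("mask must cover at least 1000 voxels")
    x = np.asarray(vol.data, dtype=np.float64)[mask]
    if np.unique(x).size < 3:
        raise DegenerateInputError("fewer than 3 distinct intensities")
    centers = np.quantile(x, [0.25, 0.50, 0.75])
    if np.unique(centers).size < 3:
        u = np.unique(x)
        centers = u[np.linspace(0, u.size - 1, 3).round().astype(int)].astype(float)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == k].mean() if (assign == k).any()
                        else centers[k] for k in range(3)])
        if np.allclose(new, centers, rtol=1e-8, atol=1e-12):
            centers = new
            break
        centers = new
    centers = np.sort(centers)
    # refine each center to the mode of its class histogram
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    refined = centers.copy()
    for k in range(3):
        xi = x[assign == k]
        if xi.size < 50 or np.ptp(xi) <= 0:
            continue
        hist, edges = np.histogram(xi, bins=101)
        smoothed = ndimage.gaussian_filter1d(hist.astype(float), 3.0)
        mids = 0.5 * (edges[:-1] + edges[1:])
        refined[k] = float(mids[np.argmax(smoothed)])
    if refined[0] < refined[1] < refined[2]:
        centers = refined
    variances = {}
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    for k, t in enumerate(TISSUES):
        xi = x[assign == k]
        variances[t] = float(np.var(xi)) if xi.size > 1 else float(np.var(x))
        variances[t] = max(variances[t], 1e-8 * float(np.var(x) + 1e-12))
    mean_fields = {t: vol.like(np.full(vol.shape, centers[k]))
                   for k, t in enumerate(TISSUES)}
    return TissueModel(mean_fields, variances, mrf_beta)


def _neighbor_count(labels: np.ndarray, klass: int, mask: np.ndarray) -> np.ndarray:
    """Number of 6-neighbours carrying label ``klass``."""
    m = (labels == klass).astype(np.float64)
    kernel = np.zeros((3, 3, 3))
    for d in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
        kernel[d] = 1.0
    out = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    out[~mask] = 0.0
    return out


def amap(vol: Volume, init: TissueModel, mask: np.ndarray,
         iters: int = 12, mrf_beta: float | None = None,
         adaptive: bool = True, adapt_fwhm_mm: float = 24.0,
         change_tol: float = 1e-3) -> PveSegmentation:
    """Adaptive maximum-a-posteriori segmentation.

    E-step: posterior proportional to the Gaussian likelihood under the
    local class means times a Potts prior ``exp(beta * #same-label
    6-neighbours)`` of the current hard labeling.  M-step: local means are
    re-estimated by Gaussian-smoothing class-weighted normalized
    intensities of eroded pure-tissue voxels (``adapt_fwhm_mm`` FWHM) into
    a shared multiplicative field that scales all three class means, which
    absorbs smooth bias while keeping the means ordered; restricting the
    estimation to eroded pure voxels keeps partial-volume mixtures from
    contaminating the class statistics.  With ``adaptive=False`` the means
    stay spatially constant.  Stops when fewer than ``change_tol`` of
    labels change, or after ``iters`` iterations.
    """
    mask = np.asarray(mask, dtype=bool)
    beta = init.mrf_beta if mrf_beta is None else mrf_beta
    data = np.asarray(vol.data, dtype=np.float64)
    glob = np.sort(np.array([float(init.mean_fields[t].data.flat[0])
                             for t in TISSUES]))
    variances = np.array([init.variances[t] for t in TISSUES])
    sigma_vox = (adapt_fwhm_mm / SIG2FWHM) / vol.voxel_size

    labels = np.zeros(vol.shape, dtype=np.int8)  # 0 = outside; 1..3 tissues
    bias = np.ones(vol.shape)
    post = None
    n_done = 0
    for it in range(iters):
        # E-step
        means = bias[None] * glob[:, None, None, None]
        logp = np.full((3,) + vol.shape, -np.inf)
        for k in range(3):
            logp[k] = (-0.5 * (data - means[k]) ** 2 / variances[k]
                       - 0.5 * np.log(variances[k]))
            if beta > 0 and it > 0:
                logp[k] = logp[k] + beta * _neighbor_count(labels, k + 1, mask)
        logp -= logp.max(axis=0, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=0, keepdims=True)
        post[:, ~mask] = 0.0
        new_labels = np.where(mask, np.argmax(post, axis=0) + 1, 0).astype(np.int8)
        changed = float(np.mean(new_labels[mask] != labels[mask]))
        labels = new_labels
        n_done = it + 1
        # M-step on eroded pure-tissue voxels
        pure = [ndimage.binary_erosion(labels == k + 1) for k in range(3)]
        if adaptive:
            num = np.zeros(vol.shape)
            den = np.zeros(vol.shape)
            for k in range(3):
                w = pure[k].astype(np.float64)
                num += ndimage.gaussian_filter(w * data / glob[k], sigma_vox)
                den += ndimage.gaussian_filter(w, sigma_vox)
            lam = den / (den + 1e-3)
            bias = lam * (num / np.maximum(den, 1e-12)) + (1.0 - lam)
        corr = data / np.maximum(bias, 1e-9) if adaptive else data
        for k in range(3):
            sel = pure[k] if pure[k].sum() > 50 else (labels == k + 1)
            if sel.sum() > 10:
                glob[k] = float(corr[sel].mean())
                variances[k] = max(float(corr[sel].var()), 1e-12)
        if not (glob[0] < glob[1] < glob[2]):
            log.warning("class means crossed during adaptation; re-sorting")
            glob = np.sort(glob)
        if it > 0 and changed < change_tol:
            break

    means = bias[None] * glob[:, None, None, None]
    model = TissueModel({t: vol.like(means[k]) for k, t in enumerate(TISSUES)},
                        {t: float(variances[k]) for k, t in enumerate(TISSUES)},
                        beta)
    prob = {t: vol.like(post[k]) for k, t in enumerate(TISSUES)}
    # provisional PVE label from the hard assignment (refined by pve())
    lab = np.where(mask, labels.astype(np.float64), 0.0)
    gm_frac = np.where(mask, np.clip(1.0 - np.abs(lab - 2.0), 0.0, 1.0), 0.0)
    return PveSegmentation(prob, vol.like(lab), vol.like(gm_frac), model,
                           mask, n_iter=n_done)


def local_intensity_transform(vol: Volume, seg: PveSegmentation) -> Volume:
    """Map intensities so local CSF/GM/WM means land on 1/3, 2/3, 1.

    A voxel-wise monotone piecewise-linear transform with anchors at the
    local class means; segments below CSF and above WM continue linearly
    with the adjacent slope.  Normalizes away both global contrast and
    smooth inhomogeneity captured by the local mean fields.
    """
    if seg.pve_label.shape != vol.shape:
        raise ValueError("segmentation grid does not match the image")
    data = np.asarray(vol.data, dtype=np.float64)
    m = seg.model.local_means()
    targets = np.array([1.0 / 3.0, 2.0 / 3.0, 1.0])
    out = np.empty_like(data)
    d_cg = np.maximum(m[1] - m[0], 1e-9)
    d_gw = np.maximum(m[2] - m[1], 1e-9)
    below = data <= m[0]
    mid1 = (~below) & (data <= m[1])
    mid2 = (data > m[1]) & (data <= m[2])
    above = data > m[2]
    out[below] = (targets[0] + (data - m[0]) / d_cg * (1.0 / 3.0))[below]
    out[mid1] = (targets[0] + (data - m[0]) / d_cg * (1.0 / 3.0))[mid1]
    out[mid2] = (targets[1] + (data - m[1]) / d_gw * (1.0 / 3.0))[mid2]
    out[above] = (targets[2] + (data - m[2]) / d_gw * (1.0 / 3.0))[above]
    return vol.like(out)


def pve(vol: Volume, seg: PveSegmentation,
        pure_tol: float = 0.0) -> PveSegmentation:
    """Partial-volume estimation over 5 classes.

    Reassigns voxels among {CSF, CSF/GM, GM, GM/WM, WM}: the mixed fraction
    of the brighter tissue is ``(I - m_low) / (m_high - m_low)`` with the
    *local* class means, clipped to [0, 1]; mixed classes are only allowed
    where the 6-neighbourhood contains both parent tissues, otherwise the
    voxel snaps to the nearer pure class.  Returns a new segmentation whose
    ``pve_label`` is continuous on [1, 3].
    """
    mask = seg.mask
    data = np.asarray(vol.data, dtype=np.float64)
    m = seg.model.local_means()
    hard = seg.hard_labels().data

    f_cg = np.clip((data - m[0]) / np.maximum(m[1] - m[0], 1e-9), 0.0, 1.0)
    f_gw = np.clip((data - m[1]) / np.maximum(m[2] - m[1], 1e-9), 0.0, 1.0)
    lab = np.where(data <= m[1], 1.0 + f_cg, 2.0 + f_gw)

    has_csf = _neighbor_count(hard, 1, mask) > 0
    has_gm = _neighbor_count(hard, 2, mask) > 0
    has_wm = _neighbor_count(hard, 3, mask) > 0
    mixed_cg = (lab > 1.0 + pure_tol) & (lab < 2.0 - pure_tol)
    mixed_gw = (lab > 2.0 + pure_tol) & (lab < 3.0 - pure_tol)
    snap_cg = mixed_cg & ~(has_csf & has_gm)
    snap_gw = mixed_gw & ~(has_gm & has_wm)
    lab = np.where(snap_cg, np.round(lab), lab)
    lab = np.where(snap_gw, np.round(lab), lab)
    lab = np.where(mask, lab, 0.0)

    csf = np.where(mask, np.clip(2.0 - lab, 0.0, 1.0), 0.0)
    gm = np.where(mask, np.clip(1.0 - np.abs(lab - 2.0), 0.0, 1.0), 0.0)
    wm = np.where(mask, np.clip(lab - 2.0, 0.0, 1.0), 0.0)
    prob = {"csf": vol.like(csf), "gm": vol.like(gm), "wm": vol.like(wm)}

    # intracranial fraction: boundary voxels darker than the local CSF mean
    # are partly background and count fractionally in volume summaries
    interior = ndimage.binary_erosion(mask)
    edge = mask & ~interior
    head_frac = mask.astype(np.float64)
    head_frac[edge] = np.clip(data[edge] / np.maximum(m[0][edge], 1e-9),
                              0.0, 1.0)
    return PveSegmentation(prob, vol.like(lab), vol.like(gm), seg.model,
                           mask, n_iter=seg.n_iter, head_fraction=head_frac)


def kappa(a: Volume | np.ndarray, b: Volume | np.ndarray, tissue: int) -> float:
    """Cohen's kappa of a binary tissue-vs-rest comparison of two labelings.

    ``tissue`` is the integer code compared against everything else.  A
    kappa of 1 means perfect correspondence; 0 is chance level.
    """
    la = np.asarray(a.data if isinstance(a, Volume) else a)
    lb = np.asarray(b.data if isinstance(b, Volume) else b)
    if la.shape != lb.shape:
        raise ValueError("label maps must share a grid")
    if la.dtype.kind == "f":
        la = np.rint(la)
    if lb.dtype.kind == "f":
        lb = np.rint(lb)
    x = (la == tissue).ravel()
    y = (lb == tissue).ravel()
    n = x.size
    p_o = float(np.mean(x == y))
    p_yes = float(x.mean()) * float(y.mean())
    p_no = (1 - float(x.mean())) * (1 - float(y.mean()))
    p_e = p_yes + p_no
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError("both maps are constant; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def tiv(seg: PveSegmentation, voxel_volume_mm3: float) -> dict[str, float]:
    """Total intracranial volume and tissue compartment volumes in ml.

    TIV sums the three tissue probabilities over the image, so partial
    voxels contribute fractionally.
    """
    hf = seg.head_fraction if seg.head_fraction is not None \
        else seg.mask.astype(float)
    out = {}
    for t in TISSUES:
        out[t + "_ml"] = float((seg.prob[t].data * hf).sum()) \
            * voxel_volume_mm3 / 1000.0
    out["tiv_ml"] = out["csf_ml"] + out["gm_ml"] + out["wm_ml"]
    return out
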