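"""Retrospective image quality control.

Rates noise, intensity inhomogeneity and spatial resolution of a scan on a
common 0.5-10.5 scale (smaller is better), combines them into an overall
rating with letter grades, and flags cohort outliers by a
correlation-to-leave-one-out-mean z-score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .denoise import masked_noise_sigma
from .segment import PveSegmentation
from .volume_io import SIG2FWHM, Volume

#: linear anchors mapping each raw measure onto the rating scale:
#: (value at rating 0.5, value at rating 10.5)
DEFAULT_ANCHORS = {
    "ncr": (0.0, 0.5),
    "icr": (0.0, 0.5),
    "res": (0.5, 3.0),
}
DEFAULT_WEIGHTS = {"ncr": 2.0, "icr": 1.0, "res": 1.0}

RATING_MIN, RATING_MAX = 0.5, 10.5


class QcUnavailableError(RuntimeError):
    """Raised when no pure-tissue voxels are available for QC."""


def rating_to_grade(rating: float) -> str:
    """Letter grade (A+ .. F) as a pure function of the rating."""
    letters = ["A", "B", "C", "D", "E", "F"]
    r = float(np.clip(rating, RATING_MIN, RATING_MAX))
    bin_idx = min(int(r - 0.5), 5)
    frac = r - 0.5 - bin_idx
    if bin_idx >= 5:
        return "F"
    letter = letters[bin_idx]
    if frac < 1.0 / 3.0:
        return letter + "+"
    if frac > 2.0 / 3.0:
        return letter + "-"
    return letter


@dataclass
class QcReport:
    """Quality measures, 0.5-10.5 ratings, grades, and overall summary."""

    ncr: float
    icr: float
    res: float
    ratings: dict[str, float]
    grades: dict[str, str]
    overall_rating: float
    overall_grade: str
    z_score: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QcReport":
        return cls(**json.loads(text))


def _rate(value: float, anchors: tuple[float, float]) -> float:
    lo, hi = anchors
    r = RATING_MIN + (value - lo) / (hi - lo) * (RATING_MAX - RATING_MIN)
    return float(np.clip(r, RATING_MIN, RATING_MAX))


def qc_rate(vol: Volume, seg: PveSegmentation,
            anchors: dict | None = None,
            weights: dict | None = None,
            bias_fwhm_mm: float = 20.0) -> QcReport:
    """Quality rating of one image given its segmentation.

    * ``ncr`` (noise-to-contrast): pseudo-residual sigma over eroded
      pure-WM voxels divided by the GM/WM contrast.
    * ``icr`` (inhomogeneity-to-contrast): standard deviation of the
      smoothed WM mean field divided by the contrast.
    * ``res``: RMS voxel size in mm.

    Each maps linearly onto [0.5, 10.5] between its anchors; the overall
    rating is the weighted mean (noise counts double by default).
    """
    anchors = {**DEFAULT_ANCHORS, **(anchors or {})}
    weights = {**DEFAULT_WEIGHTS, **(weights or {})}
    data = np.asarray(vol.data, dtype=np.float64)

    wm_pure = ndimage.binary_erosion(seg.prob["wm"].data > 0.9)
    gm_pure = ndimage.binary_erosion(seg.prob["gm"].data > 0.9)
    if not wm_pure.any() or not gm_pure.any():
        raise QcUnavailableError("no pure-tissue voxels after erosion")

    contrast = abs(float(data[wm_pure].mean()) - float(data[gm_pure].mean()))
    contrast = max(contrast, 1e-9)

    ncr = masked_noise_sigma(vol, wm_pure) / contrast

    # low-frequency WM intensity field: masked normalized smoothing
    sigma_vox = (bias_fwhm_mm / SIG2FWHM) / vol.voxel_size
    w = wm_pure.astype(np.float64)
    num = ndimage.gaussian_filter(data * w, sigma_vox)
    den = ndimage.gaussian_filter(w, sigma_vox)
    fld = num[wm_pure] / np.maximum(den[wm_pure], 1e-12)
    icr = float(np.std(fld)) / contrast

    res = float(np.sqrt(np.mean(vol.voxel_size ** 2)))

    values = {"ncr": ncr, "icr": icr, "res": res}
    ratings = {k: _rate(values[k], anchors[k]) for k in values}
    grades = {k: rating_to_grade(r) for k, r in ratings.items()}
    wsum = sum(weights.values())
    overall = sum(weights[k] * ratings[k] for k in ratings) / wsum
    return QcReport(ncr=ncr, icr=icr, res=res, ratings=ratings, grades=grades,
                    overall_rating=overall, overall_grade=rating_to_grade(overall))


def sample_homogeneity(gm_maps: list[np.ndarray],
                       flag_z: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Cohort homogeneity z-scores from leave-one-out correlations.

    For each subject, ``r_i`` is the Pearson correlation of its (registered,
    smoothed) GM map with the mean of all other subjects; ``z_i``
    standardizes ``1 - r_i`` across the cohort.  Returns ``(z, flagged)``
    where subjects with ``|z| > flag_z`` are flagged as outliers.
    """
    if len(gm_maps) < 3:
        raise ValueError("need at least 3 subjects")
    M = np.stack([np.asarray(m, dtype=np.float64).ravel() for m in gm_maps])
    n = M.shape[0]
    total = M.sum(axis=0)
    r = np.empty(n)
    for i in range(n):
        loo = (total - M[i]) / (n - 1)
        r[i] = np.corrcoef(M[i], loo)[0, 1]
    d = 1.0 - r
    sd = d.std()
    z = (d - d.mean()) / (sd if sd > 1e-15 else 1.0)
    return z, np.abs(z) > flag_z
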