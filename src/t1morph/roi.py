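"""Region-based morphometry: atlas warping and per-region summaries.

Regions come from integer label volumes (voxel-based) or per-vertex label
arrays (surface-based) with a lookup table mapping codes to names; code 0
is unlabeled.  Regional gray-matter volume uses the continuous tissue
fractions so partial voxels contribute proportionally; regional thickness
is the area-weighted vertex mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .register import DeformationField, warp
from .segment import PveSegmentation, TISSUES
from .surface import SurfaceMesh, VertexScalars
from .volume_io import Volume

log = logging.getLogger(__name__)


@dataclass
class Atlas:
    """Integer label map (volumetric or surface) plus a code -> name table."""

    labels: Volume | np.ndarray
    lut: dict[int, str]

    def __post_init__(self) -> None:
        lab = self.labels.data if isinstance(self.labels, Volume) else self.labels
        lab = np.asarray(lab)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.rint(lab)):
                raise ValueError("atlas labels must be integers")
        present = set(np.unique(lab).astype(int)) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"label codes missing from lut: {sorted(missing)}")

    def codes(self) -> list[int]:
        return sorted(self.lut)


def warp_atlas(atlas: Atlas, field: DeformationField) -> Atlas:
    """Pull a template-space label volume into native space (nearest label)."""
    if not isinstance(atlas.labels, Volume):
        raise ValueError("warp_atlas needs a volumetric atlas")
    lab = atlas.labels
    if not np.issubdtype(lab.data.dtype, np.integer):
        if not np.allclose(lab.data, np.rint(lab.data)):
            raise ValueError("atlas labels must be integers")
        lab = lab.like(np.rint(lab.data).astype(np.int32))
    warped = warp(lab, field, interp="nearest")
    return Atlas(warped, dict(atlas.lut))


def regional_volumes(seg: PveSegmentation, atlas: Atlas,
                     voxel_volume_mm3: float | None = None) -> pd.DataFrame:
    """Per-region tissue volumes in ml from the continuous fractions.

    Unlabeled voxels (code 0) are excluded; a region absent from the label
    volume yields a zero row with a warning.
    """
    if not isinstance(atlas.labels, Volume):
        raise ValueError("regional_volumes needs a volumetric atlas")
    lab = np.asarray(atlas.labels.data).astype(int)
    if lab.shape != seg.pve_label.shape:
        raise ValueError("atlas and segmentation grids differ")
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = seg.pve_label.voxel_volume_mm3
    fracs = {"gm": np.asarray(seg.gm_fraction.data, dtype=np.float64)}
    fracs["csf"] = np.asarray(seg.prob["csf"].data, dtype=np.float64)
    fracs["wm"] = np.asarray(seg.prob["wm"].data, dtype=np.float64)
    rows = []
    for code in atlas.codes():
        m = lab == code
        if not m.any():
            log.warning("region %d (%s) absent from label volume",
                        code, atlas.lut[code])
        row = {"code": code, "region": atlas.lut[code]}
        for t in TISSUES:
            row[f"{t}_ml"] = float(fracs[t][m].sum()) * voxel_volume_mm3 / 1000.0
        rows.append(row)
    return pd.DataFrame(rows)


def regional_thickness(thickness: VertexScalars, atlas: Atlas,
                       mesh: SurfaceMesh) -> pd.DataFrame:
    """Area-weighted mean thickness and surface area per region."""
    lab = np.asarray(atlas.labels).astype(int).ravel()
    if lab.size != mesh.n_vertices:
        raise ValueError("label count must equal vertex count")
    if not (lab != 0).any():
        raise ValueError("atlas labels all unlabeled")
    area = mesh.vertex_areas()
    vals = thickness.values
    rows = []
    for code in atlas.codes():
        m = lab == code
        if m.any():
            mean_mm = float(np.average(vals[m], weights=area[m]))
            a = float(area[m].sum())
        else:
            log.warning("region %d (%s) has no vertices", code, atlas.lut[code])
            mean_mm, a = 0.0, 0.0
        rows.append({"code": code, "region": atlas.lut[code],
                     "mean_mm": mean_mm, "area_mm2": a})
    return pd.DataFrame(rows)


def hemisphere_atlas(grid: Volume, mask: np.ndarray | None = None) -> Atlas:
    """Toy two-region atlas splitting a volume at the mid-sagittal plane."""
    ijk = np.indices(grid.shape)
    x_world = (grid.affine[0, 0] * ijk[0] + grid.affine[0, 1] * ijk[1]
               + grid.affine[0, 2] * ijk[2] + grid.affine[0, 3])
    lab = np.where(x_world < 0, 1, 2).astype(np.int16)
    if mask is not None:
        lab[~np.asarray(mask, dtype=bool)] = 0
    return Atlas(grid.like(lab), {1: "left", 2: "right"})
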