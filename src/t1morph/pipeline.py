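"""Cross-sectional pipeline orchestration.

``run_subject`` executes the voxel stream (denoise, segment, QC, TIV) and
optionally the surface stream (distances, projection-based thickness,
central surface, folding metrics) for a single image.  ``run_study`` runs a
cohort: per-subject processing, iterative template construction,
warp+modulate+smooth of the GM maps, TFCE permutation statistics for the
voxel-based analysis, a common spherical sampling of thickness for the
surface-based analysis, and FDR-corrected regional tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import denoise as dn
from . import qc as qcmod
from . import register as reg
from . import roi as roimod
from . import segment as segmod
from . import stats as statsmod
from . import surface as surfmod
from . import surfmetrics as smmod
from .volume_io import Volume, read_volume, smooth_fwhm, write_volume

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


_CONFIG_FIELDS = {
    "denoise": True,
    "segment": True,
    "qc": True,
    "surface": True,
    "metrics": True,
    "sanlm_beta": 1.0,
    "mrf_beta": 0.1,
    "amap_iters": 12,
    "adapt_fwhm_mm": 24.0,
    "vbm_fwhm_mm": 6.0,
    "sbm_fwhm_mm": 12.0,
    "template_iters": 2,
    "n_perm": 200,
    "alpha": 0.05,
    "tail": "one",
    "seed": 0,
    "out_dir": "",
}


@dataclass
class PipelineConfig:
    """Stage toggles and parameters; round-trips through a JSON document."""

    denoise: bool = True
    segment: bool = True
    qc: bool = True
    surface: bool = True
    metrics: bool = True
    sanlm_beta: float = 1.0
    mrf_beta: float = 0.1
    amap_iters: int = 12
    adapt_fwhm_mm: float = 24.0
    vbm_fwhm_mm: float = 6.0
    sbm_fwhm_mm: float = 12.0
    template_iters: int = 2
    n_perm: int = 200
    alpha: float = 0.05
    tail: str = "one"
    seed: int = 0
    out_dir: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        doc = json.loads(text)
        unknown = set(doc) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def run_subject(img, config: PipelineConfig | None = None,
                out_prefix: str | Path | None = None,
                return_objects: bool = False):
    """Process one image through the voxel (and optional surface) stream.

    ``img`` is a path or a Volume.  Returns a JSON-serializable report with
    class means, TIV, QC ratings, mean thickness and per-stage runtimes;
    the surface stream only runs if the voxel stream succeeded.  With
    ``return_objects=True`` also returns the intermediate objects
    (segmentation, surfaces) for cohort-level reuse.
    """
    config = config or PipelineConfig()
    objects: dict = {}
    report: dict = {"config": asdict(config), "stages": [], "outputs": []}
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                report["stages"].append(name)
        return _Ctx()

    with stage("read_volume"):
        vol = read_volume(img) if not isinstance(img, Volume) else img

    if config.denoise:
        with stage("denoise"):
            noise = dn.estimate_noise(vol)
            vol_d = dn.sanlm(vol, noise, beta=config.sanlm_beta)
            report["sigma_global"] = noise.sigma_global
    else:
        vol_d = vol

    seg = None
    if config.segment:
        with stage("segment"):
            mask = segmod.head_mask(vol_d)
            model = segmod.init_classes(vol_d, mask, mrf_beta=config.mrf_beta)
            seg0 = segmod.amap(vol_d, model, mask, iters=config.amap_iters,
                               adapt_fwhm_mm=config.adapt_fwhm_mm)
            seg = segmod.pve(vol_d, seg0)
            objects["seg"] = seg
            vols = segmod.tiv(seg, vol.voxel_volume_mm3)
            report["tiv_ml"] = vols["tiv_ml"]
            report["compartments_ml"] = vols
            report["class_means"] = {
                t: float(np.mean(seg.model.mean_fields[t].data[mask]))
                for t in segmod.TISSUES}
            report["amap_iterations"] = seg.n_iter

        if config.qc:
            with stage("qc"):
                rep = qcmod.qc_rate(vol, seg)
                report["qc"] = json.loads(rep.to_json())

    if config.surface and seg is not None:
        with stage("surface"):
            wmd, csfd = surfmod.boundary_distances(seg)
            gm_mask = np.asarray(seg.gm_fraction.data) > 0.5
            thick, level = surfmod.pbt_thickness(wmd, csfd, gm_mask)
            central = surfmod.extract_central_surface(level)
            white, pial, t_vtx = surfmod.offset_surfaces(central, level, thick)
            objects.update(central=central, white=white, pial=pial,
                           thickness=t_vtx, level=level)
            report["mean_thickness_mm"] = float(
                np.average(t_vtx.values, weights=central.vertex_areas()))
            report["surface_genus"] = central.genus
            report["surface_euler"] = central.euler_characteristic
        if config.metrics:
            with stage("metrics"):
                gyr = smmod.gyrification(central)
                dep = smmod.sulcal_depth(central)
                report["mean_gyrification"] = float(np.mean(gyr.values))
                report["mean_sulcal_depth"] = float(np.mean(dep.values))
    report["timings_s"] = timings

    if out_prefix is not None and seg is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        for t in segmod.TISSUES:
            p = f"{out_prefix}_p{'cgw'.index(t[0]) + 1}.nii.gz"
            write_volume(seg.prob[t], p)
            report["outputs"].append(p)
        write_volume(seg.pve_label, f"{out_prefix}_pve.nii.gz")
        report["outputs"].append(f"{out_prefix}_pve.nii.gz")
        with open(f"{out_prefix}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        report["outputs"].append(f"{out_prefix}_report.json")
    if return_objects:
        return report, objects
    return report


def _common_sphere_thickness(central: surfmod.SurfaceMesh,
                             t_vtx: surfmod.VertexScalars,
                             directions: np.ndarray) -> np.ndarray:
    """Resample per-vertex thickness onto common unit-sphere directions.

    Spherically parameterizes the subject surface and takes the value of
    the nearest mapped vertex for each reference direction — a minimal
    stand-in for surface registration that works because the phantom
    cohort shares its topology and approximate orientation.
    """
    sphere = smmod.spherical_parameterize(central)
    from scipy.spatial import cKDTree
    tree = cKDTree(sphere.coords)
    _, idx = tree.query(directions)
    return t_vtx.values[idx]


def run_study(subjects: list[dict], config: PipelineConfig | None = None,
              out_dir: str | Path | None = None) -> dict:
    """Cohort analysis: VBM + SBM TFCE maps and FDR-corrected ROI tables.

    ``subjects`` is a list of dicts with keys ``volume`` (Volume or path),
    ``group`` ("A"/"B"), optional ``tiv_ml`` and covariates.  Group A is
    tested against group B in the positive direction (one-tailed by
    default).  Returns a report containing the four result sets: VBM map,
    volumetric ROI table, SBM map, surface ROI table.
    """
    config = config or PipelineConfig()
    groups = [s["group"] for s in subjects]
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError("run_study expects exactly two groups")
    order = np.argsort([uniq.index(g) for g in groups], kind="stable")
    subjects = [subjects[i] for i in order]
    groups = [s["group"] for s in subjects]
    n_a = groups.count(uniq[0])
    n_b = groups.count(uniq[1])

    per_subject = []
    per_objects = []
    for s in subjects:
        rep, obj = run_subject(s["volume"], config, return_objects=True)
        per_subject.append(rep)
        per_objects.append(obj)
    segs = [o["seg"] for o in per_objects]
    gm_native = [seg.gm_fraction for seg in segs]

    tiv = np.array([s.get("tiv_ml") or per_subject[i]["tiv_ml"]
                    for i, s in enumerate(subjects)])

    # --- template + VBM stream
    template = reg.build_template(gm_native, n_iter=config.template_iters,
                                  levels=2, iters_per_level=15)
    warped_mod = []
    for gm in gm_native:
        fld = reg.register_diffeo(template, gm, levels=2, iters_per_level=15)
        w = reg.warp(gm, fld)
        m = reg.modulate(w, fld.jacobian)
        warped_mod.append(smooth_fwhm(m, config.vbm_fwhm_mm))
    Y = np.stack([w.data.ravel() for w in warped_mod])
    Y = statsmod.global_scaling_tiv(Y, tiv)
    design = statsmod.Design.two_group(n_a, n_b, tail=config.tail)
    p_vbm, tfce_obs, _ = statsmod.permutation_fwe(
        Y, design, statsmod.TfceParams(), n_perm=config.n_perm,
        seed=config.seed, shape=template.shape)
    z, flagged = qcmod.sample_homogeneity([w.data for w in warped_mod])

    # --- volumetric ROI stream
    atlas = roimod.hemisphere_atlas(gm_native[0])
    roi_rows = [roimod.regional_volumes(seg, atlas) for seg in segs]
    roi_gm = np.array([[r["gm_ml"][i] for i in range(len(atlas.codes()))]
                       for r in roi_rows])
    t_roi = statsmod.fit_glm(statsmod.global_scaling_tiv(roi_gm, tiv), design)
    from scipy import stats as sps
    dof = design.matrix.shape[0] - design.matrix.shape[1]
    p_roi = sps.t.sf(t_roi, dof)
    rej, thr = statsmod.fdr_bh(p_roi, q=config.alpha)
    roi_table = pd.DataFrame({
        "code": atlas.codes(),
        "region": [atlas.lut[c] for c in atlas.codes()],
        "t": t_roi, "p": p_roi, "significant": rej})

    # --- SBM stream on a common spherical sampling
    sbm = None
    if config.surface:
        import trimesh.creation
        ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        directions = np.asarray(ico.vertices)
        thick_common = []
        ref = surfmod.SurfaceMesh(directions, np.asarray(ico.faces))
        for obj in per_objects:
            tv = surfmod.VertexScalars(_common_sphere_thickness(
                obj["central"], obj["thickness"], directions))
            tv = surfmod.smooth_surface_scalar(ref, tv, config.sbm_fwhm_mm)
            thick_common.append(tv.values)
        Ys = np.stack(thick_common)
        adj = statsmod.mesh_adjacency(np.asarray(ico.faces), len(directions))
        p_sbm, tfce_sbm, _ = statsmod.permutation_fwe(
            Ys, design, statsmod.TfceParams.for_mesh(),
            n_perm=config.n_perm, seed=config.seed + 1,
            adjacency=adj, vertex_area=ref.vertex_areas())
        surf_atlas = roimod.Atlas(
            np.where(directions[:, 0] < 0, 1, 2).astype(int),
            {1: "left", 2: "right"})
        rows = []
        for i in range(Ys.shape[0]):
            tb = roimod.regional_thickness(
                surfmod.VertexScalars(Ys[i]), surf_atlas, ref)
            rows.append(tb["mean_mm"].to_numpy())
        t_sroi = statsmod.fit_glm(np.stack(rows), design)
        p_sroi = sps.t.sf(t_sroi, dof)
        srej, _ = statsmod.fdr_bh(p_sroi, q=config.alpha)
        sroi_table = pd.DataFrame({
            "region": ["left", "right"], "t": t_sroi, "p": p_sroi,
            "significant": srej})
        sbm = {"p_corr": p_sbm, "tfce": tfce_sbm, "roi_table": sroi_table,
               "n_significant": int((p_sbm <= config.alpha).sum())}

    report = {
        "n_subjects": len(subjects),
        "groups": {uniq[0]: n_a, uniq[1]: n_b},
        "per_subject": per_subject,
        "homogeneity_z": z.tolist(),
        "homogeneity_flagged": flagged.tolist(),
        "vbm": {"p_corr": p_vbm, "tfce": tfce_obs,
                "n_significant": int((p_vbm <= config.alpha).sum())},
        "roi_table": roi_table,
        "sbm": sbm,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(template.like(p_vbm), out_dir / "vbm_pcorr.nii.gz")
        roi_table.to_csv(out_dir / "roi_volumes.csv", index=False)
        if sbm is not None:
            sbm["roi_table"].to_csv(out_dir / "roi_thickness.csv", index=False)
    return report


def load_manifest(path) -> list[dict]:
    """Read a cohort manifest CSV (columns: path, group, optional tiv_ml)."""
    df = pd.read_csv(path)
    subjects = []
    for _, row in df.iterrows():
        s = {"volume": row["path"], "group": str(row["group"])}
        if "tiv_ml" in df.columns and not pd.isna(row["tiv_ml"]):
            s["tiv_ml"] = float(row["tiv_ml"])
        subjects.append(s)
    return subjects
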