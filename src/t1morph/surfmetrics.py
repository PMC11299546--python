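"""Folding measures on central-surface meshes.

Four complementary descriptors of cortical folding: gyrification (absolute
mean curvature), sulcal depth (distance to the enclosing convex hull),
cortical complexity (fractal dimension from band-limited spherical-harmonic
reconstructions of the surface), and the surface ratio (local area relative
to a flat disk).  All are deterministic and invariant under rigid motion
and vertex reindexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import ConvexHull, cKDTree
from scipy.special import sph_harm_y

from .surface import SurfaceMesh, VertexScalars, cotangent_laplacian

log = logging.getLogger(__name__)


class TopologyError(ValueError):
    pass


@dataclass
class SphereMap:
    """Bijective map of a genus-0 mesh onto the unit sphere."""

    coords: np.ndarray            # (n_vertices, 3), unit norm
    area_distortion: np.ndarray   # per-vertex mapped/original area ratio
    mesh: SurfaceMesh

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("sphere map coordinates must be unit norm")


# ---------------------------------------------------------------------------
# gyrification: absolute mean curvature


def mean_curvature_signed(mesh: SurfaceMesh) -> np.ndarray:
    """Signed mean curvature H (1/mm) from the cotangent Laplace-Beltrami.

    The mean-curvature normal is ``Delta x = -2 H n`` with n the outward
    vertex normal, so a sphere of radius r gives H = +1/r everywhere.
    """
    L = cotangent_laplacian(mesh, clamp=False)
    area = np.maximum(mesh.vertex_areas(), 1e-12)
    delta = np.column_stack([L @ mesh.vertices[:, a] for a in range(3)])
    delta /= area[:, None]
    normals = mesh.vertex_normals()
    h_signed = -0.5 * np.einsum("ij,ij->i", delta, normals)
    return h_signed


def gyrification(mesh: SurfaceMesh, neighborhood_mm: float = 3.0
                 ) -> VertexScalars:
    """Absolute mean curvature |H|, area-averaged over a local neighbourhood.

    The neighbourhood average (default 3 mm Euclidean radius) suppresses
    per-vertex discretization noise of the curvature operator.
    """
    tm = mesh.to_trimesh()
    if tm.area_faces.min() <= 1e-12:
        raise ValueError("mesh has degenerate faces")
    h_abs = np.abs(mean_curvature_signed(mesh))
    if neighborhood_mm <= 0:
        return VertexScalars(h_abs, "gyrification", "1/mm")
    area = mesh.vertex_areas()
    tree = cKDTree(mesh.vertices)
    pairs = tree.query_ball_point(mesh.vertices, neighborhood_mm, workers=-1)
    out = np.empty_like(h_abs)
    for i, idx in enumerate(pairs):
        w = area[idx]
        out[i] = np.average(h_abs[idx], weights=w)
    return VertexScalars(out, "gyrification", "1/mm")


# ---------------------------------------------------------------------------
# sulcal depth: distance to the enclosing hull


def sulcal_depth(mesh: SurfaceMesh, sqrt_transform: bool = False
                 ) -> VertexScalars:
    """Per-vertex Euclidean distance from the surface to its convex hull.

    Zero on convex surfaces; optionally square-root transformed (a variance
    stabilization some pipelines apply; off by default).
    """
    from .surface import point_surface_distance
    hull = ConvexHull(mesh.vertices)
    hull_mesh = SurfaceMesh(mesh.vertices[hull.vertices],
                            _reindex_faces(hull))
    depth = point_surface_distance(mesh.vertices, hull_mesh)
    if sqrt_transform:
        depth = np.sqrt(depth)
    return VertexScalars(depth, "sulcal_depth", "mm")


def _reindex_faces(hull: ConvexHull) -> np.ndarray:
    remap = {v: i for i, v in enumerate(hull.vertices)}
    return np.vectorize(remap.get)(hull.simplices)


# ---------------------------------------------------------------------------
# spherical parameterization


def spherical_parameterize(mesh: SurfaceMesh, n_iter: int = 400,
                           relax: float = 0.5) -> SphereMap:
    """Map a genus-0 mesh onto the unit sphere.

    Vertices are first projected radially from the centroid, which is exact
    (bijective, zero extra distortion) for star-shaped surfaces such as
    folded phantom cortices and the identity for a sphere.  If the radial
    projection flips any spherical triangle, iterative uniform-Laplacian
    inflation with per-step reprojection relaxes the map until the flips
    disappear.  Raises if the input is not genus 0 or if flips persist.
    """
    if mesh.genus != 0:
        raise TopologyError(f"spherical mapping needs genus 0, got {mesh.genus}")
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    if _count_flipped(v, mesh.faces) > 0:
        n = mesh.n_vertices
        edges = mesh.edges()
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        A = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        deg = np.asarray(A.sum(axis=1)).ravel()
        for it in range(n_iter):
            nb_mean = (A @ v) / deg[:, None]
            v_new = (1 - relax) * v + relax * nb_mean
            v_new -= v_new.mean(axis=0)
            v_new /= np.linalg.norm(v_new, axis=1, keepdims=True)
            move = float(np.max(np.linalg.norm(v_new - v, axis=1)))
            v = v_new
            if move < 1e-8 or (it % 10 == 9
                               and _count_flipped(v, mesh.faces) == 0):
                break
    if _count_flipped(v, mesh.faces) > 0:
        raise TopologyError("spherical map contains flipped triangles")
    orig_area = np.maximum(mesh.vertex_areas(), 1e-12)
    mapped_area = SurfaceMesh(v, mesh.faces).vertex_areas()
    ratio = (mapped_area / mapped_area.sum()) / (orig_area / orig_area.sum())
    return SphereMap(v, ratio, mesh)


def _count_flipped(sphere_coords: np.ndarray, faces: np.ndarray) -> int:
    """Spherical triangles whose orientation disagrees with the majority."""
    a = sphere_coords[faces[:, 0]]
    b = sphere_coords[faces[:, 1]]
    c = sphere_coords[faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c))
    majority = np.sign(np.median(signed))
    return int(np.sum(np.sign(signed) != majority))


# ---------------------------------------------------------------------------
# fractal dimension from spherical-harmonic reconstructions


def _real_sph_harm_basis(coords: np.ndarray, l_max: int) -> np.ndarray:
    """Real spherical-harmonic design matrix at unit-sphere points."""
    x, y, z = coords.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))          # polar
    phi = np.arctan2(y, x)                            # azimuth
    cols = []
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * ylm.imag)
            elif m == 0:
                cols.append(ylm.real)
            else:
                cols.append(np.sqrt(2.0) * ylm.real)
    return np.column_stack(cols)


def _degree_slices(l_max: int):
    start = 0
    for l in range(l_max + 1):
        width = 2 * l + 1
        yield l, slice(start, start + width)
        start += width


def fractal_dimension(mesh: SurfaceMesh, sphere: SphereMap | None = None,
                      l_max: int = 32, l_min_fit: int = 8,
                      return_details: bool = False):
    """Cortical complexity as a fractal dimension.

    Vertex coordinates are expanded in spherical harmonics over the sphere
    map; surfaces reconstructed band-limited at degrees l = 2, 4, ..., l_max
    gain area as folds re-enter, and ``FD = 2 + slope(log area vs log l)``
    over the scaling regime ``l in [l_min_fit, l_max]``.  A perfectly smooth
    sphere has constant reconstructed area, hence FD = 2.
    """
    if l_max < 8:
        raise ValueError("l_max must be >= 8")
    if sphere is None:
        sphere = spherical_parameterize(mesh)
    # the expansion needs comfortably more samples than coefficients
    l_fit = l_max
    while (l_fit + 1) ** 2 > mesh.n_vertices // 2 and l_fit > 8:
        l_fit -= 2
    if l_fit < l_max:
        log.info("l_max reduced from %d to %d for %d vertices",
                 l_max, l_fit, mesh.n_vertices)
        l_max = l_fit
    B = _real_sph_harm_basis(sphere.coords, l_max)
    # area-weighted least squares so irregular sampling does not bias the fit
    w = np.sqrt(np.maximum(mesh.vertex_areas(), 1e-12))
    coef, *_ = np.linalg.lstsq(B * w[:, None], mesh.vertices * w[:, None],
                               rcond=None)
    degrees = np.arange(2, l_max + 1, 2)
    areas = []
    for l_cut in degrees:
        keep = np.zeros(B.shape[1], dtype=bool)
        for l, sl in _degree_slices(l_max):
            if l <= l_cut:
                keep[sl] = True
        recon = B[:, keep] @ coef[keep]
        areas.append(SurfaceMesh(recon, mesh.faces).to_trimesh().area)
    areas = np.asarray(areas)
    if np.any(np.diff(areas) < -0.02 * areas[:-1]):
        raise RuntimeError("spherical-harmonic areas are not monotone; "
                           f"per-degree areas: {areas.tolist()}")
    sel = degrees >= l_min_fit
    slope = np.polyfit(np.log(degrees[sel]), np.log(areas[sel]), 1)[0]
    fd = 2.0 + float(slope)
    if return_details:
        return fd, degrees, areas
    return fd


# ---------------------------------------------------------------------------
# surface ratio


def surface_ratio(mesh: SurfaceMesh, radius_mm: float = 20.0,
                  subdiv: int = 3) -> VertexScalars:
    """Local surface area inside a Euclidean ball over the flat-disk area.

    For every vertex, the mesh area contained in ``ball(v, r)`` is divided
    by ``pi r^2``; a flat patch gives 1, folding pushes the ratio above 1.
    Boundary-crossing triangles are clipped by recursive subdivision
    (``4^subdiv`` sub-triangles, centroid-inside test).
    """
    v = mesh.vertices
    f = mesh.faces
    tm = mesh.to_trimesh()
    fa = tm.area_faces
    centroids = v[f].mean(axis=1)
    # circumscribed radius of each face around its centroid
    tri_r = np.linalg.norm(v[f] - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(centroids)
    disk = np.pi * radius_mm ** 2
    out = np.empty(mesh.n_vertices)

    # precompute subdivided barycentric sampling of a reference triangle
    bary, w_frac = _subdivision_centroids(subdiv)

    for i in range(mesh.n_vertices):
        center = v[i]
        cand = tree.query_ball_point(center, radius_mm + tri_r.max())
        cand = np.asarray(cand, dtype=int)
        if cand.size == 0:
            out[i] = 0.0
            continue
        d = np.linalg.norm(centroids[cand] - center, axis=1)
        fully_in = cand[d + tri_r[cand] <= radius_mm]
        crossing = cand[(d - tri_r[cand] <= radius_mm)
                        & (d + tri_r[cand] > radius_mm)]
        area = fa[fully_in].sum()
        if crossing.size:
            tri = v[f[crossing]]                     # (m, 3, 3)
            pts = np.einsum("kb,mbx->mkx", bary, tri)
            inside = (np.linalg.norm(pts - center, axis=2) <= radius_mm)
            area += (fa[crossing] * inside.mean(axis=1)).sum()
        out[i] = area / disk
    return VertexScalars(out, "surface_ratio", "")


def _subdivision_centroids(depth: int) -> tuple[np.ndarray, float]:
    """Barycentric centroids of the 4^depth uniform triangle subdivision.

    All sub-triangles have equal area, so the inside fraction of their
    centroids estimates the clipped area fraction directly.
    """
    n = 2 ** depth
    cents = []
    for i in range(n):
        for j in range(n - i):
            # upright: (i, j), (i+1, j), (i, j+1)
            cents.append(((3 * i + 1), (3 * j + 1)))
            if i + j <= n - 2:
                # inverted: (i+1, j), (i, j+1), (i+1, j+1)
                cents.append(((3 * i + 2), (3 * j + 2)))
    ij = np.asarray(cents, dtype=np.float64) / (3.0 * n)
    bary = np.column_stack([ij[:, 0], ij[:, 1], 1.0 - ij.sum(axis=1)])
    return bary, 1.0 / bary.shape[0]
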