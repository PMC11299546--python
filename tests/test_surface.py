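import numpy as np
import pytest

from t1morph import (boundary_distances, extract_central_surface,
                     pbt_thickness, refine_thickness_fs, sample_to_surface,
                     smooth_surface_scalar)
from t1morph.surface import (ExtractionError, SurfaceMesh, VertexScalars,
                             offset_surfaces, point_surface_distance,
                             sample_volume_at_points, _point_triangle_distances)
from t1morph.segment import PveSegmentation
from t1morph.volume_io import Volume
from conftest import icosphere_mesh, plane_mesh, radius_volume, seg_from_truth


def synthetic_seg(csf, gm, wm, affine=None):
    aff = np.eye(4) if affine is None else affine
    mask = (csf + gm + wm) > 0.5
    return PveSegmentation(
        prob={"csf": Volume(csf, aff), "gm": Volume(gm, aff),
              "wm": Volume(wm, aff)},
        pve_label=Volume(1.0 * csf + 2.0 * gm + 3.0 * wm, aff),
        gm_fraction=Volume(gm, aff), model=None, mask=mask)


class TestBoundaryDistances:
    def test_shell_distances_match_analytic(self, truth_seg, shell_phantom):
        vol, truth = shell_phantom
        wmd, csfd = boundary_distances(truth_seg)
        ijk = np.indices(vol.shape).reshape(3, -1).T
        r = np.linalg.norm(vol.voxel_to_world(ijk), axis=1).reshape(vol.shape)
        gm = truth.hard_labels.data == 2
        assert np.abs(wmd.data[gm] - np.clip(r - 10, 0, None)[gm]).mean() < 0.25
        assert np.abs(csfd.data[gm] - np.clip(14 - r, 0, None)[gm]).mean() < 0.25

    def test_gm_voxel_adjacent_to_wm_subvoxel_offset(self, truth_seg,
                                                     shell_phantom):
        vol, truth = shell_phantom
        wmd, _ = boundary_distances(truth_seg)
        gm = truth.hard_labels.data == 2
        wm = truth.fractions["wm"].data >= 0.5  # the measured boundary region
        from scipy import ndimage
        adjacent = gm & ndimage.binary_dilation(wm) & ~wm
        # sub-voxel boundary placement: strictly inside the one-voxel gap
        assert (wmd.data[adjacent] < 1.0).mean() > 0.95
        assert wmd.data[adjacent].max() < 1.1
        assert wmd.data[adjacent].mean() < 0.9

    def test_distance_sum_bounded_below_by_separation(self, truth_seg,
                                                      shell_phantom):
        _, truth = shell_phantom
        wmd, csfd = boundary_distances(truth_seg)
        gm = truth.hard_labels.data == 2
        # the WM and CSF boundaries are 4 mm apart everywhere
        assert (wmd.data[gm] + csfd.data[gm] >= 4.0 - 0.5).all()

    def test_all_gm_ball_csfd_is_distance_to_surface(self):
        n = 32
        aff = np.eye(4)
        aff[:3, 3] = (0.5 - n / 2)
        ijk = np.indices((n, n, n), dtype=float)
        r = np.sqrt(sum((ijk[a] + aff[a, 3]) ** 2 for a in range(3)))
        gm = (r <= 10).astype(float)
        seg = synthetic_seg(np.zeros_like(gm), gm, np.zeros_like(gm), aff)
        _, csfd = boundary_distances(seg)
        inside = r <= 8
        assert np.abs(csfd.data[inside] - (10 - r[inside])).max() < 0.5

    def test_no_gm_raises(self):
        z = np.zeros((10, 10, 10))
        seg = synthetic_seg(np.ones_like(z), z, z)
        with pytest.raises(ValueError):
            boundary_distances(seg)


class TestPbtThickness:
    def test_shell_thickness_recovered(self, truth_seg, shell_phantom):
        _, truth = shell_phantom
        wmd, csfd = boundary_distances(truth_seg)
        gm = truth.hard_labels.data == 2
        thick, _ = pbt_thickness(wmd, csfd, gm)
        assert thick.data[gm].mean() == pytest.approx(4.0, abs=0.2)

    def test_thickness_bounded_by_distance_sum(self, truth_seg,
                                               shell_phantom):
        _, truth = shell_phantom
        wmd, csfd = boundary_distances(truth_seg)
        gm = truth.hard_labels.data == 2
        thick, _ = pbt_thickness(wmd, csfd, gm)
        assert (thick.data[gm] <= wmd.data[gm] + csfd.data[gm] + 1e-9).all()

    def test_blurred_sulcus_half_voxel_gap(self):
        """A GM slab whose sulcus is only a half-voxel CSF gap must read the
        same thickness as the identical slab with a fully open sulcus;
        rounding the gap to hard labels instead reads the doubled
        slab-to-slab distance through the invisible sulcus."""
        nx, ny, nz = 24, 24, 26
        bank_sel = np.s_[4:-4, 4:-4, 8:12]

        def build(blurred):
            csf = np.zeros((nx, ny, nz))
            gm = np.zeros((nx, ny, nz))
            wm = np.zeros((nx, ny, nz))
            wm[:, :, :8] = 1          # WM below z=7.5
            gm[:, :, 8:12] = 1        # bank under test
            csf[:, :, 12] = 0.5       # half-voxel gap
            gm[:, :, 12] = 0.5
            if blurred:               # second bank + WM above
                gm[:, :, 13:16] = 1
                gm[:, :, 16] = 0.5
                wm[:, :, 16] = 0.5
                wm[:, :, 17:] = 1
            else:                     # open sulcus: CSF above the gap
                csf[:, :, 13:] = 1
            return synthetic_seg(csf, gm, wm)

        def thickness(seg, gm_mask):
            wmd, csfd = boundary_distances(seg)
            t, _ = pbt_thickness(wmd, csfd, gm_mask)
            return t.data[bank_sel].mean()

        gm_mask = np.zeros((nx, ny, nz), dtype=bool)
        gm_mask[:, :, 8:12] = True
        t_open = thickness(build(False), gm_mask)
        t_blurred = thickness(build(True), gm_mask)
        assert t_blurred == pytest.approx(t_open, rel=0.10)

        # hard-label route: the half-voxel gap rounds away entirely
        seg = build(True)
        hard_csf = (seg.prob["csf"].data > 0.5).astype(float)
        hard_gm = ((seg.prob["gm"].data >= 0.5)
                   & (seg.prob["wm"].data < 0.5)).astype(float)
        hard_wm = (seg.prob["wm"].data >= 0.5).astype(float)
        hard_csf[:, :, :2] = 1  # outer CSF so the naive route has a target
        hard_wm[:, :, :2] = 0
        wmd_h, csfd_h = boundary_distances(
            synthetic_seg(hard_csf, hard_gm, hard_wm))
        naive = (wmd_h.data + csfd_h.data)[bank_sel].mean()
        assert naive > 1.6 * t_blurred


class TestExtractCentralSurface:
    @pytest.fixture(scope="class")
    def shell_surface(self, truth_seg, shell_phantom):
        _, truth = shell_phantom
        wmd, csfd = boundary_distances(truth_seg)
        gm = truth.hard_labels.data == 2
        thick, level = pbt_thickness(wmd, csfd, gm)
        return extract_central_surface(level), level, thick

    def test_sphere_topology(self, shell_surface):
        mesh, _, _ = shell_surface
        assert mesh.euler_characteristic == 2
        assert mesh.genus == 0

    def test_sphere_area(self, shell_surface):
        mesh, _, _ = shell_surface
        assert mesh.to_trimesh().area == pytest.approx(4 * np.pi * 12 ** 2,
                                                       rel=0.02)

    def test_central_between_white_and_pial(self, shell_surface):
        mesh, level, thick = shell_surface
        white, pial, t_vtx = offset_surfaces(mesh, level, thick)
        lw = sample_volume_at_points(level, white.vertices)
        lp = sample_volume_at_points(level, pial.vertices)
        # level increases from white (negative) to pial (positive)
        assert (lw < 0).mean() > 0.95
        assert (lp > 0).mean() > 0.95

    def test_no_sign_change_raises(self):
        v = Volume(np.ones((8, 8, 8)), np.eye(4))
        with pytest.raises(ExtractionError):
            extract_central_surface(v)


class TestRefineThicknessFs:
    def test_parallel_planes(self):
        p1 = plane_mesh(half=10.0, n=21)
        p2 = SurfaceMesh(p1.vertices + [0, 0, 3.0], p1.faces)
        t = refine_thickness_fs(p1, p2)
        interior = np.abs(p1.vertices[:, :2]).max(axis=1) < 6
        assert np.allclose(t.values[interior], 3.0, atol=1e-9)

    def test_concentric_spheres(self):
        white = icosphere_mesh(10.0, 3)
        pial = SurfaceMesh(white.vertices * 1.4, white.faces)
        t = refine_thickness_fs(white, pial)
        assert np.allclose(t.values, 4.0, rtol=0.01)

    def test_matches_brute_force_oracle(self):
        white = icosphere_mesh(8.0, 2)
        rng = np.random.default_rng(0)
        pial = SurfaceMesh(white.vertices * 1.3
                           + rng.normal(0, 0.1, white.vertices.shape),
                           white.faces)
        t = refine_thickness_fs(white, pial)

        def brute(points, mesh):
            tri = mesh.vertices[mesh.faces]
            return np.array([_point_triangle_distances(
                np.broadcast_to(p, (len(tri), 3)), tri).min()
                for p in points])

        oracle = 0.5 * (brute(white.vertices, pial)
                        + brute(pial.vertices, white))
        assert np.abs(t.values - oracle).max() < 1e-6

    def test_mismatched_meshes_rejected(self):
        a = icosphere_mesh(10.0, 2)
        b = icosphere_mesh(10.0, 3)
        with pytest.raises(ValueError):
            refine_thickness_fs(a, b)


class TestSampleToSurface:
    def test_constant_volume_gives_constant(self):
        vol = Volume(np.full((40, 40, 40), 7.0),
                     np.eye(4) * np.diag([1, 1, 1, 1]))
        vol.affine[:3, 3] = -19.5
        mesh = icosphere_mesh(12.0, 3)
        T = VertexScalars(np.full(mesh.n_vertices, 4.0))
        out = sample_to_surface(vol, mesh, T, 0.3, "equidistant")
        assert np.allclose(out.values, 7.0)

    def test_flat_slab_equivolume_equals_equidistant(self):
        vol = radius_volume(64)
        mesh = plane_mesh(half=10.0, n=21)
        T = VertexScalars(np.full(mesh.n_vertices, 4.0))
        zero_h = np.zeros(mesh.n_vertices)
        e1 = sample_to_surface(vol, mesh, T, 0.3, "equidistant")
        e2 = sample_to_surface(vol, mesh, T, 0.3, "equivolume",
                               mean_curvature=zero_h)
        assert np.abs(e1.values - e2.values).max() < 1e-6

    def test_spherical_shell_closed_form(self):
        """At mid-depth in a 10/14 mm shell, the equi-volume sample sits at
        ((10^3+14^3)/2)^(1/3) ~ 12.32 mm, outside the equidistant midpoint."""
        vol = radius_volume(64)
        mesh = icosphere_mesh(12.0, 3)
        T = VertexScalars(np.full(mesh.n_vertices, 4.0))
        eq = sample_to_surface(vol, mesh, T, 0.5, "equidistant")
        ev = sample_to_surface(vol, mesh, T, 0.5, "equivolume")
        r_expected = ((10 ** 3 + 14 ** 3) / 2) ** (1 / 3)
        assert eq.values.mean() == pytest.approx(12.0, abs=0.05)
        assert ev.values.mean() == pytest.approx(r_expected, abs=0.05)

    def test_alpha_out_of_range(self):
        mesh = icosphere_mesh(12.0, 2)
        T = VertexScalars(np.full(mesh.n_vertices, 4.0))
        with pytest.raises(ValueError):
            sample_to_surface(radius_volume(32), mesh, T, 1.5)


class TestSmoothSurfaceScalar:
    def test_constant_unchanged(self):
        mesh = icosphere_mesh(12.0, 3)
        s = VertexScalars(np.full(mesh.n_vertices, 2.5))
        out = smooth_surface_scalar(mesh, s, 12.0)
        assert np.allclose(out.values, 2.5, atol=1e-9)

    def test_area_weighted_mean_preserved(self):
        mesh = icosphere_mesh(12.0, 3)
        rng = np.random.default_rng(1)
        s = VertexScalars(rng.normal(size=mesh.n_vertices))
        out = smooth_surface_scalar(mesh, s, 8.0)
        a = mesh.vertex_areas()
        assert np.average(out.values, weights=a) == pytest.approx(
            np.average(s.values, weights=a), abs=1e-6)

    def test_impulse_attains_requested_fwhm(self):
        mesh = icosphere_mesh(20.0, 4)
        s = np.zeros(mesh.n_vertices)
        s[0] = 1.0
        out = smooth_surface_scalar(mesh, VertexScalars(s), 12.0)
        u = mesh.vertices / 20.0
        geo = np.arccos(np.clip(u @ u[0], -1, 1)) * 20.0
        half = out.values.max() / 2
        # smallest geodesic radius at which the profile falls below half max
        order = np.argsort(geo)
        prof = out.values[order]
        below = np.flatnonzero(prof < half)
        fwhm = 2 * geo[order][below[0]]
        assert fwhm == pytest.approx(12.0, rel=0.15)
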