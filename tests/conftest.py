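import numpy as np
import pytest
import trimesh

from t1morph import PhantomSpec, generate_phantom
from t1morph.segment import PveSegmentation
from t1morph.surface import SurfaceMesh
from t1morph.volume_io import Volume


@pytest.fixture(scope="session")
def shell_phantom():
    """Noiseless concentric-shell phantom (WM r=10, GM 4 mm, CSF 3 mm)."""
    spec = PhantomSpec(noise_percent=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def folded_phantom():
    spec = PhantomSpec(noise_percent=0.0, fold_amplitude=2.0, seed=1)
    return generate_phantom(spec)


def seg_from_truth(truth) -> PveSegmentation:
    """Ideal segmentation assembled from phantom ground truth.

    Copies every array so tests can mutate the segmentation without
    corrupting the session-scoped phantom fixtures.
    """
    fr = truth.fractions
    mask = (fr["csf"].data + fr["gm"].data + fr["wm"].data) > 0.5
    lab = truth.hard_labels.data.astype(float)
    return PveSegmentation(
        prob={k: fr[k].copy() for k in ("csf", "gm", "wm")},
        pve_label=truth.hard_labels.like(lab),
        gm_fraction=fr["gm"].copy(),
        model=None, mask=mask)


@pytest.fixture(scope="session")
def truth_seg(shell_phantom):
    return seg_from_truth(shell_phantom[1])


def icosphere_mesh(radius=12.0, subdivisions=3) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices, dtype=float),
                       np.asarray(ico.faces))


def plane_mesh(half=20.0, n=41) -> SurfaceMesh:
    xs = np.linspace(-half, half, n)
    X, Y = np.meshgrid(xs, xs)
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
    return SurfaceMesh(verts, np.asarray(faces))


def folded_mesh(radius=12.0, amp=2.4, freq=6, subdivisions=4) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices)
    theta = np.arccos(np.clip(u[:, 2], -1, 1))
    phi = np.arctan2(u[:, 1], u[:, 0])
    r = radius + amp * np.sin(freq * theta) * np.sin(freq * phi)
    return SurfaceMesh(u * r[:, None], np.asarray(ico.faces))


def radius_volume(n=64) -> Volume:
    """Volume whose value at every point is its distance from the origin."""
    aff = np.eye(4)
    aff[:3, 3] = -(n - 1) / 2.0
    ijk = np.indices((n, n, n), dtype=float)
    world = np.stack([ijk[a] + aff[a, 3] for a in range(3)])
    return Volume(np.sqrt((world ** 2).sum(axis=0)), aff)
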