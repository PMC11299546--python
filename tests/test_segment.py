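import numpy as np
import pytest

from t1morph import (PhantomSpec, amap, generate_phantom, head_mask,
                     init_classes, kappa, local_intensity_transform, pve, tiv)
from t1morph.segment import (DegenerateInputError, TISSUES,
                             UndefinedKappaError)
from t1morph.volume_io import Volume
from conftest import seg_from_truth


@pytest.fixture(scope="module")
def segmented_shell(shell_phantom):
    vol, truth = shell_phantom
    mask = head_mask(vol)
    model = init_classes(vol, mask)
    seg = pve(vol, amap(vol, model, mask))
    return vol, truth, mask, model, seg


class TestInitClasses:
    def test_noiseless_means_match_generator(self, segmented_shell):
        _, _, _, model, _ = segmented_shell
        for t, expected in zip(TISSUES, (40.0, 80.0, 120.0)):
            got = float(model.mean_fields[t].data.flat[0])
            assert got == pytest.approx(expected, rel=0.05)

    def test_means_ascending(self, segmented_shell):
        _, _, _, model, _ = segmented_shell
        m = [float(model.mean_fields[t].data.flat[0]) for t in TISSUES]
        assert m[0] < m[1] < m[2]

    def test_binary_image_degenerate(self):
        data = np.where(np.arange(16)[:, None, None] < 8, 0.0, 1.0)
        v = Volume(np.broadcast_to(data, (16, 16, 16)).copy(), np.eye(4))
        with pytest.raises(DegenerateInputError):
            init_classes(v, np.ones(v.shape, dtype=bool))


class TestAmap:
    def test_noiseless_gm_kappa_above_099(self, segmented_shell):
        _, truth, _, _, seg = segmented_shell
        k = kappa(seg.hard_labels(), truth.hard_labels, 2)
        assert k >= 0.99

    def test_beta_zero_nonadaptive_equals_ml(self, shell_phantom):
        """With the MRF prior off and constant means, the posterior argmax
        must coincide with per-voxel maximum likelihood under the same
        final class model."""
        vol, _ = shell_phantom
        mask = head_mask(vol)
        model = init_classes(vol, mask)
        seg = amap(vol, model, mask, mrf_beta=0.0, adaptive=False)
        m = np.array([float(seg.model.mean_fields[t].data.flat[0])
                      for t in TISSUES])
        var = np.array([seg.model.variances[t] for t in TISSUES])
        logl = np.stack([
            -0.5 * (vol.data - m[k]) ** 2 / var[k] - 0.5 * np.log(var[k])
            for k in range(3)])
        ml = np.where(mask, np.argmax(logl, axis=0) + 1, 0)
        assert np.array_equal(seg.hard_labels().data, ml)

    def test_bias_adaptive_beats_constant(self):
        spec = PhantomSpec(noise_percent=1.0, bias_percent=10.0, seed=5)
        vol, truth = generate_phantom(spec)
        mask = head_mask(vol)
        model = init_classes(vol, mask)
        k_on = kappa(amap(vol, model, mask, adaptive=True).hard_labels(),
                     truth.hard_labels, 2)
        k_off = kappa(amap(vol, model, mask, adaptive=False).hard_labels(),
                      truth.hard_labels, 2)
        assert k_on > k_off

    def test_axis_flip_equivariance(self):
        """No spatial priors: flipping the input flips the output."""
        spec = PhantomSpec(noise_percent=3.0, fold_amplitude=2.0, seed=8)
        vol, _ = generate_phantom(spec)
        mask = head_mask(vol)
        seg = amap(vol, init_classes(vol, mask), mask)
        flipped = Volume(vol.data[::-1].copy(), vol.affine)
        mask_f = mask[::-1].copy()
        seg_f = amap(flipped, init_classes(flipped, mask_f), mask_f)
        assert np.array_equal(seg.hard_labels().data[::-1],
                              seg_f.hard_labels().data)


class TestLocalIntensityTransform:
    def test_anchor_and_midpoints(self, segmented_shell):
        vol, _, mask, _, seg = segmented_shell
        out = local_intensity_transform(vol, seg)
        m = seg.model.local_means()
        wm_like = np.isclose(vol.data, m[2], atol=1e-6) & mask
        assert np.allclose(out.data[wm_like], 1.0, atol=1e-6)
        mid = np.isclose(vol.data, 0.5 * (m[1] + m[2]), atol=1e-6) & mask
        if mid.any():
            assert np.allclose(out.data[mid], 5.0 / 6.0, atol=1e-6)

    def test_histogram_modes_at_canonical_values(self, segmented_shell):
        vol, _, mask, _, seg = segmented_shell
        out = local_intensity_transform(vol, seg)
        hist, edges = np.histogram(out.data[mask], bins=300, range=(0, 1.2))
        centers = 0.5 * (edges[:-1] + edges[1:])
        for target in (1.0 / 3.0, 2.0 / 3.0, 1.0):
            near = np.abs(centers - target) < 0.05
            peak = centers[near][np.argmax(hist[near])]
            assert peak == pytest.approx(target, abs=0.01)


class TestPve:
    def test_pure_and_mixed_labels(self, segmented_shell):
        vol, _, mask, _, seg = segmented_shell
        m = seg.model.local_means()
        at_wm = np.isclose(vol.data, m[2], atol=1e-9) & mask
        assert np.allclose(seg.pve_label.data[at_wm], 3.0)
        mid = np.isclose(vol.data, 0.5 * (m[1] + m[2]), atol=0.05) & mask
        mixed = seg.pve_label.data[mid]
        if mixed.size:
            assert np.allclose(mixed, 2.5, atol=0.01)

    def test_gm_volume_matches_truth(self, segmented_shell):
        _, truth, _, _, seg = segmented_shell
        est = seg.gm_fraction.data.sum()
        true = truth.fractions["gm"].data.sum()
        assert est == pytest.approx(true, rel=0.02)

    def test_probabilities_sum_to_one_in_mask(self, segmented_shell):
        _, _, mask, _, seg = segmented_shell
        total = sum(seg.prob[t].data for t in TISSUES)
        assert np.abs(total[mask] - 1.0).max() < 1e-4


class TestKappa:
    def test_identity_is_exactly_one(self, shell_phantom):
        """Perfect correspondence between a segmentation and itself."""
        _, truth = shell_phantom
        assert kappa(truth.hard_labels, truth.hard_labels, 2) == 1.0

    def test_complementary_maps_give_minus_one(self):
        a = np.zeros((10, 10, 10), dtype=int)
        a[:5] = 1
        b = 1 - a
        assert kappa(a, b, 1) == pytest.approx(-1.0)

    def test_hand_confusion_example(self):
        # 2x2 confusion (4 TP, 1 FN, 1 FP, 4 TN) on 10 voxels -> kappa 0.6
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0]).reshape(10, 1, 1)
        b = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0]).reshape(10, 1, 1)
        assert kappa(a, b, 1) == pytest.approx(0.6)

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, size=(12, 12, 12))
        b = rng.integers(0, 4, size=(12, 12, 12))
        for tissue in (1, 2, 3):
            ours = kappa(a, b, tissue)
            ref = cohen_kappa_score((a == tissue).ravel(),
                                    (b == tissue).ravel())
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_constant_maps_undefined(self):
        a = np.zeros((5, 5, 5), dtype=int)
        b = np.ones((5, 5, 5), dtype=int)
        with pytest.raises(UndefinedKappaError):
            kappa(a, b, 2)


class TestTiv:
    def test_matches_phantom_truth(self, segmented_shell):
        vol, truth, _, _, seg = segmented_shell
        vols = tiv(seg, vol.voxel_volume_mm3)
        assert vols["tiv_ml"] == pytest.approx(truth.tiv_ml, rel=0.03)

    def test_compartments_sum_to_tiv(self, segmented_shell):
        vol, _, _, _, seg = segmented_shell
        vols = tiv(seg, vol.voxel_volume_mm3)
        assert vols["csf_ml"] + vols["gm_ml"] + vols["wm_ml"] == \
            pytest.approx(vols["tiv_ml"], abs=1e-12)

    def test_empty_segmentation_zero(self, shell_phantom):
        vol, truth = shell_phantom
        seg = seg_from_truth(truth)
        for t in TISSUES:
            seg.prob[t].data[:] = 0.0
        assert tiv(seg, 1.0)["tiv_ml"] == 0.0
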