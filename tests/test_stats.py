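import numpy as np
import pytest
from scipy import ndimage

from t1morph import (Design, TfceParams, fdr_bh, fit_glm, global_scaling_tiv,
                     permutation_fwe, tfce)
from t1morph.stats import DesignError, mesh_adjacency, tfce_grid, tfce_mesh


def tfce_grid_oracle(stat, params):
    """Independent TFCE: explicit per-cluster loop over thresholds."""
    out = np.zeros_like(stat)
    dh = stat.max() / params.n_steps
    for k in range(1, params.n_steps + 1):
        h = k * dh
        lab, n = ndimage.label(stat >= h)
        for i in range(1, n + 1):
            sel = lab == i
            out[sel] += sel.sum() ** params.E * h ** params.H * dh
    return out


class TestFitGlm:
    def test_two_sample_t_hand_value(self):
        Y = np.array([1.0, 2, 3, 4, 5, 6])[:, None]
        t = fit_glm(Y, Design.two_group(3, 3))
        # pooled-variance two-sample t for {1,2,3} vs {4,5,6}
        assert t[0] == pytest.approx(-3.6742346, abs=1e-6)

    def test_contrast_orthogonal_to_shift(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(8, 5)) + 100.0  # common shift
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        d = Design(X, np.array([0.0, 1.0]))
        t = fit_glm(Y, d)
        t_shifted = fit_glm(Y + 50.0, d)
        assert np.allclose(t, t_shifted, atol=1e-9)

    def test_duplicated_regressor_rejected(self):
        x = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), x, x])
        with pytest.raises(DesignError, match="rank"):
            Design(X, np.array([0.0, 1.0, 0.0]))

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        Y = rng.normal(size=(10, 4))
        d = Design(X, np.array([0.0, 1.0]))
        beta = np.linalg.pinv(X) @ Y
        resid = Y - X @ beta
        assert np.abs(X.T @ resid).max() < 1e-8


class TestGlobalScaling:
    def test_equal_tiv_unchanged(self):
        Y = np.arange(12.0).reshape(3, 4)
        out = global_scaling_tiv(Y, np.full(3, 1500.0))
        assert np.allclose(out, Y)

    def test_double_tiv_halves_data(self):
        Y = np.ones((2, 3))
        out = global_scaling_tiv(Y, np.array([1.0, 3.0]))
        # mean TIV = 2; subject 2 has TIV 3 -> scaled by 2/3
        assert np.allclose(out[1], 2.0 / 3.0)

    def test_removes_proportional_tiv_effect(self):
        """Volumes generated proportional to TIV correlate strongly with
        TIV before scaling and essentially not at all after."""
        rng = np.random.default_rng(2)
        tiv = rng.uniform(1200, 1800, 30)
        Y = tiv[:, None] * rng.uniform(0.8, 1.2, (1, 50)) \
            + rng.normal(0, 5.0, (30, 50))
        r_before = np.corrcoef(Y.sum(axis=1), tiv)[0, 1]
        out = global_scaling_tiv(Y, tiv)
        r_after = np.corrcoef(out.sum(axis=1), tiv)[0, 1]
        assert r_before > 0.95
        assert abs(r_after) < 0.3

    def test_non_positive_tiv_rejected(self):
        with pytest.raises(ValueError):
            global_scaling_tiv(np.ones((2, 2)), np.array([1.0, 0.0]))


class TestTfce:
    def test_all_zero_map(self):
        assert np.all(tfce_grid(np.zeros((6, 6, 6))) == 0)

    def test_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(3)
        params = TfceParams()
        for _ in range(3):
            stat = np.clip(ndimage.gaussian_filter(
                rng.standard_normal((12, 12, 12)), 1.2), 0, None) * 5
            enh = tfce_grid(stat, params)
            oracle = tfce_grid_oracle(stat, params)
            assert np.abs(enh - oracle).max() <= 0.01 * max(oracle.max(), 1e-12)

    def test_single_voxel_closed_form(self):
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 3.0
        params = TfceParams()
        enh = tfce_grid(stat, params)
        dh = 3.0 / params.n_steps
        closed = sum((k * dh) ** params.H * dh
                     for k in range(1, params.n_steps + 1))
        assert enh[2, 2, 2] == pytest.approx(closed, rel=1e-12)

    def test_mesh_matches_per_cluster_oracle(self):
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=3)  # 642 vertices
        faces = np.asarray(ico.faces)
        nv = len(ico.vertices)
        adj = mesh_adjacency(faces, nv)
        rng = np.random.default_rng(4)
        stat = np.clip(np.asarray(ico.vertices)[:, 2]
                       + 0.3 * rng.standard_normal(nv), 0, None) * 4
        params = TfceParams.for_mesh()
        enh = tfce_mesh(stat, adj, None, params)
        # oracle: breadth-first cluster search per threshold
        import networkx as nx
        G = nx.Graph()
        G.add_nodes_from(range(nv))
        for f in faces:
            G.add_edges_from([(f[0], f[1]), (f[1], f[2]), (f[2], f[0])])
        oracle = np.zeros(nv)
        dh = stat.max() / params.n_steps
        for k in range(1, params.n_steps + 1):
            h = k * dh
            sub = G.subgraph(np.flatnonzero(stat >= h))
            for comp in nx.connected_components(sub):
                idx = list(comp)
                oracle[idx] += len(idx) ** params.E * h ** params.H * dh
        assert np.abs(enh - oracle).max() <= 0.01 * max(oracle.max(), 1e-12)

    def test_monotone_in_stat_height(self):
        """Raising any voxel's statistic never lowers any enhanced value
        (exact for a fixed integration step)."""
        rng = np.random.default_rng(5)
        stat = np.clip(ndimage.gaussian_filter(
            rng.standard_normal((8, 8, 8)), 1.0), 0, None) * 3
        params = TfceParams(dh=stat.max() / 30)
        base = tfce_grid(stat, params)
        for _ in range(100):
            idx = tuple(rng.integers(0, 8, 3))
            bumped = stat.copy()
            bumped[idx] += rng.uniform(0.1, 2.0)
            enh = tfce_grid(bumped, params)
            assert (enh >= base - 1e-9 * base.max()).all()


class TestPermutationFwe:
    def test_p_floor(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(12, 27))
        d = Design.two_group(6, 6)
        p, _, _ = permutation_fwe(Y, d, TfceParams(n_steps=20), n_perm=99,
                                  seed=0, shape=(3, 3, 3))
        assert (p >= 1.0 / 100.0).all()
        assert (p <= 1.0).all()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(12, 27))
        d = Design.two_group(6, 6)
        p1, _, n1 = permutation_fwe(Y, d, TfceParams(n_steps=20), n_perm=99,
                                    seed=3, shape=(3, 3, 3))
        p2, _, n2 = permutation_fwe(Y, d, TfceParams(n_steps=20), n_perm=99,
                                    seed=3, shape=(3, 3, 3))
        assert np.array_equal(p1, p2)
        assert np.array_equal(n1, n2)

    def test_block_consistent_reordering_invariance(self):
        """Permutation p-values are unchanged when observations and their
        block labels are reordered together (exhaustive enumeration)."""
        rng = np.random.default_rng(8)
        n = 8
        Y = rng.normal(size=(n, 27))
        Y[:4] += 0.8
        blocks = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        X = np.column_stack([np.concatenate([np.ones(4), np.zeros(4)]),
                             np.ones(n)])
        d = Design(X, np.array([1.0, 0.0]), blocks=blocks)
        p1, _, _ = permutation_fwe(Y, d, TfceParams(n_steps=20), n_perm=10 ** 6,
                                   seed=0, shape=(3, 3, 3))
        order = rng.permutation(n)
        d2 = Design(X[order], np.array([1.0, 0.0]), blocks=blocks[order])
        p2, _, _ = permutation_fwe(Y[order], d2, TfceParams(n_steps=20),
                                   n_perm=10 ** 6, seed=0, shape=(3, 3, 3))
        assert np.allclose(p1, p2)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(9)
        shape = (6, 6, 6)
        n = 16
        Y = rng.normal(size=(n, 216))
        effect = np.zeros(shape)
        effect[1:4, 1:4, 1:4] = 2.0
        Y[:8] += effect.ravel()
        d = Design.two_group(8, 8)
        p, _, _ = permutation_fwe(Y, d, TfceParams(), n_perm=199, seed=1,
                                  shape=shape)
        sig = p.ravel() <= 0.05
        assert sig[effect.ravel() > 0].mean() > 0.5


class TestFdrBh:
    def test_hand_example_four_rejections(self):
        p = np.array([0.001, 0.01, 0.02, 0.03, 0.5])
        mask, thr = fdr_bh(p, q=0.05)
        assert mask.sum() == 4
        assert thr == pytest.approx(0.03)

    def test_all_ones_no_rejections(self):
        mask, thr = fdr_bh(np.ones(10), q=0.05)
        assert mask.sum() == 0

    def test_matches_exhaustive_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        for _ in range(100):
            m = rng.integers(3, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            mask, _ = fdr_bh(p, q=0.05)
            # exhaustive step-up oracle
            order = np.argsort(p)
            ranked = p[order]
            k_best = 0
            for k in range(1, m + 1):
                if ranked[k - 1] <= 0.05 * k / m:
                    k_best = k
            oracle = np.zeros(m, dtype=bool)
            if k_best:
                oracle[order[:k_best]] = True
            assert np.array_equal(mask, oracle)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mask, ref)
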