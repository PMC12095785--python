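"""Embedding fidelity, alignment, and dispersion exactness."""

import numpy as np
import pytest
from scipy.linalg import qr

from plastmap import features, gradients, synthgen
from plastmap.gradients import (GradientSet, between_dispersion, build_affinity,
                                diffusion_embed, dispersion_pipeline,
                                dispersion_wide, normalize_to_control,
                                procrustes_align, within_dispersion)


def two_block_affinity(n=12, strong=1.0, weak=0.05):
    A = np.full((n, n), weak)
    h = n // 2
    A[:h, :h] = strong
    A[h:, h:] = strong
    np.fill_diagonal(A, 1.0)
    return A


class TestAffinity:
    def test_identical_rows_unit_affinity(self):
        F = two_block_affinity(8)
        A = build_affinity(F, sparsity_q=0.5)
        # rows 0 and 1 are identical -> zero angle -> affinity 1
        assert A[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_half_affinity(self):
        # block-diagonal feature: thresholded rows of different blocks share no
        # support -> cosine 0 -> 1 - (π/2)/π = 0.5
        F = np.zeros((4, 4))
        F[:2, :2] = 0.8
        F[2:, 2:] = 0.8
        np.fill_diagonal(F, 1.0)
        A = build_affinity(F, sparsity_q=0.5)
        assert A[0, 2] == pytest.approx(0.5, abs=1e-12)

    def test_row_sparsity_contract(self, rng):
        X = rng.normal(size=(20, 20))
        F = (X + X.T) / 2
        n = 20
        keep = int(np.ceil(0.10 * n))
        thresh = np.zeros_like(F)
        order = np.argsort(F, axis=1)
        rows = np.arange(n)[:, None]
        thresh[rows, order[:, -keep:]] = F[rows, order[:, -keep:]]
        assert ((thresh != 0).sum(axis=1) == keep).all()

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            build_affinity(rng.normal(size=(5, 5)))


class TestDiffusionEmbed:
    def test_g1_separates_two_blocks(self):
        A = two_block_affinity(12)
        g = diffusion_embed(A, k=3)
        signs = np.sign(g.components[:, 0])
        assert len(set(signs[:6])) == 1 and len(set(signs[6:])) == 1
        assert signs[0] != signs[6]

    def test_matches_dense_eigensolver_oracle(self, rng):
        """Independent oracle: nonsymmetric eig of the Markov matrix itself."""
        X = np.abs(rng.normal(size=(18, 18))) + 0.1
        W = (X + X.T) / 2
        np.fill_diagonal(W, 1.0)
        alpha = 0.5
        d = W.sum(1)
        Wa = W / np.outer(d ** alpha, d ** alpha)
        M = Wa / Wa.sum(1, keepdims=True)
        evals, evecs = np.linalg.eig(M)
        idx = np.argsort(evals.real)[::-1]
        evals, evecs = evals.real[idx], evecs.real[:, idx]
        g = diffusion_embed(W, k=4, alpha=alpha, t=0.0)
        np.testing.assert_allclose(g.eigenvalues, evals[1:5], atol=1e-8)
        for j in range(4):
            c = np.corrcoef(g.components[:, j], evecs[:, j + 1])[0, 1]
            assert abs(c) > 0.999

    def test_permutation_equivariance(self, rng):
        X = np.abs(rng.normal(size=(14, 14))) + 0.05  # generic: no spectral ties
        A = (X + X.T) / 2
        g = diffusion_embed(A, k=3)
        perm = rng.permutation(14)
        gp = diffusion_embed(A[np.ix_(perm, perm)], k=3)
        np.testing.assert_allclose(gp.components, g.components[perm], atol=1e-8)

    def test_eigenvalue_contract(self, rng):
        X = np.abs(rng.normal(size=(15, 15)))
        W = (X + X.T) / 2
        g = diffusion_embed(W, k=5)
        assert (np.diff(g.eigenvalues) <= 1e-12).all()
        assert (g.eigenvalues <= 1.0 + 1e-12).all()

    def test_disconnected_graph_rejected(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embed(W, k=2)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            diffusion_embed(two_block_affinity(8), k=8)


class TestProcrustes:
    def test_identity(self, rng):
        comps = rng.normal(size=(20, 4))
        g = GradientSet(comps, np.linspace(1, 0.5, 4))
        aligned = procrustes_align(g, g)
        np.testing.assert_allclose(aligned.components, comps, atol=1e-12)

    def test_recovers_random_orthogonal_rotation(self, rng):
        comps = rng.normal(size=(25, 5))
        Q, _ = qr(rng.normal(size=(5, 5)))
        ref = GradientSet(comps, np.ones(5))
        src = GradientSet(comps @ Q, np.ones(5))
        aligned = procrustes_align(src, ref)
        np.testing.assert_allclose(aligned.components, comps, atol=1e-8)

    def test_never_increases_distance(self, rng):
        ref = GradientSet(rng.normal(size=(15, 3)), np.ones(3))
        src = GradientSet(rng.normal(size=(15, 3)), np.ones(3))
        before = np.linalg.norm(src.components - ref.components)
        after = np.linalg.norm(
            procrustes_align(src, ref).components - ref.components)
        assert after <= before + 1e-12

    def test_shape_mismatch_rejected(self, rng):
        a = GradientSet(rng.normal(size=(10, 3)), np.ones(3))
        b = GradientSet(rng.normal(size=(10, 4)), np.ones(4))
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_align(a, b)


class TestDispersion:
    def grads(self, pts):
        pts = np.asarray(pts, dtype=float)
        return GradientSet(pts, np.ones(pts.shape[1]))

    def test_hand_computed_within(self):
        g = self.grads([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        # distances² to centroid (1/3,1/3,0): 2/9, 5/9, 5/9 -> sum 4/3
        assert within_dispersion(g, [0, 1, 2]) == pytest.approx(4 / 3, abs=1e-14)

    def test_hand_computed_between(self):
        g = self.grads([[0, 0, 0], [3, 4, 0]])
        assert between_dispersion(g, [0], [1]) == pytest.approx(5.0, abs=1e-14)

    def test_coincident_and_identical_sets(self):
        g = self.grads([[1, 2, 3]] * 4)
        assert within_dispersion(g, [0, 1, 2, 3]) == 0.0
        assert between_dispersion(g, [0, 1], [2, 3]) == 0.0

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(10, 3))
        g1 = self.grads(pts)
        g2 = self.grads(pts + np.array([5.0, -2.0, 0.3]))
        assert within_dispersion(g1, range(10)) == pytest.approx(
            within_dispersion(g2, range(10)), abs=1e-10)

    def test_orthogonal_transform_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        Q, _ = qr(rng.normal(size=(3, 3)))
        g1, g2 = self.grads(pts), self.grads(pts @ Q)
        assert within_dispersion(g1, range(6)) == pytest.approx(
            within_dispersion(g2, range(6)), abs=1e-10)
        assert between_dispersion(g1, range(6), range(6, 12)) == pytest.approx(
            between_dispersion(g2, range(6), range(6, 12)), abs=1e-10)

    def test_symmetry_and_errors(self, rng):
        g = self.grads(rng.normal(size=(8, 3)))
        assert between_dispersion(g, [0, 1], [2, 3]) == pytest.approx(
            between_dispersion(g, [2, 3], [0, 1]))
        with pytest.raises(ValueError):
            within_dispersion(g, [0])
        with pytest.raises(ValueError):
            between_dispersion(g, [], [1])

    def test_uses_first_three_gradients_only(self, rng):
        pts = rng.normal(size=(6, 5))
        g5 = GradientSet(pts, np.ones(5))
        g3 = GradientSet(pts[:, :3].copy(), np.ones(3))
        assert within_dispersion(g5, range(6)) == pytest.approx(
            within_dispersion(g3, range(6)))


class TestNormalizeToControl:
    def test_hand_case_and_properties(self):
        np.testing.assert_allclose(
            normalize_to_control([2.0, 4.0], [1.0, 3.0]), [0.0, 2.0])
        vals = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(normalize_to_control(vals, [0.0]), vals)
        ctrl = np.array([4.0, 6.0])
        assert normalize_to_control(ctrl, ctrl).mean() == pytest.approx(0.0)
        with pytest.raises(ValueError, match="empty"):
            normalize_to_control(vals, [])


@pytest.fixture(scope="module")
def plant():
    cfg = synthgen.SynthConfig(n_subjects=6, n_nodes=42, n_genes=5,
                               n_timepoints=120, seed=11)
    geom = synthgen.gen_geometry(cfg)
    eff = np.abs(synthgen.gen_subject_effects(cfg)) + 0.5  # all positive
    ts = synthgen.gen_timeseries(cfg, geom, eff)
    mats = {(s, sess, "FC"): features.build_fc(ts[sess][s])
            for sess in cfg.sessions for s in range(cfg.n_subjects)}
    return cfg, geom, mats


class TestDispersionPipeline:
    def test_identical_sessions_zero_change(self, plant):
        cfg, geom, mats = plant
        dup = {(0, "pre", "FC"): mats[(0, "pre", "FC")],
               (0, "post", "FC"): mats[(0, "pre", "FC")].copy()}
        table, _ = dispersion_pipeline(dup, geom.network_labels)
        change = table[table.session == "post-pre"]["value"]
        np.testing.assert_allclose(change, 0.0, atol=1e-10)

    def test_row_count_contract(self, plant):
        cfg, geom, mats = plant
        table, _ = dispersion_pipeline(mats, geom.network_labels)
        n_sess = table[table.session.isin(cfg.sessions)]
        assert len(n_sess) == cfg.n_subjects * cfg.n_sessions * 1 * 3
        change = table[table.session == "post-pre"]
        assert len(change) == cfg.n_subjects * 3

    def test_planted_fpn_widening_positive_mean(self, plant):
        cfg, geom, mats = plant
        table, _ = dispersion_pipeline(mats, geom.network_labels)
        fpn = dispersion_wide(table, "post-pre", "FC")["FPN-within"]
        assert fpn.mean() > 0

    def test_low_noise_sessions_shrink_changes(self):
        """Two sessions from one feature matrix + noise: changes → 0 with noise."""
        rng = np.random.default_rng(4)
        base = np.abs(rng.normal(size=(30, 30)))
        base = (base + base.T) / 2
        labels = (["VN"] * 5 + ["FPN"] * 5 + ["other1"] * 5 + ["other2"] * 5
                  + ["other3"] * 4 + ["other4"] * 3 + ["other5"] * 3)
        spread = []
        for noise in (0.05, 0.005):
            pert = rng.normal(size=(2, 30, 30))
            mats = {}
            for i, sess in enumerate(("pre", "post")):
                p = noise * (pert[i] + pert[i].T) / 2
                mats[(0, sess, "FC")] = base + p
            table, _ = dispersion_pipeline(mats, labels, k=5)
            spread.append(np.abs(table[table.session == "post-pre"]["value"]).mean())
        assert spread[1] < spread[0]
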