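import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from bbpls.gradients import (
    GradientConfig,
    cosine_affinity,
    diffusion_embedding,
    group_mean_fc,
    procrustes_align,
    row_threshold,
)
from bbpls.synthetic import matrix_to_edges


def _dense_oracle(A, alpha=0.5, n_components=10):
    """Independent diffusion-map oracle on the explicitly formed Markov
    operator, right eigenvectors normalized to unit stationary-weighted
    norm and scaled by lambda/(1-lambda)."""
    A = A.copy().astype(float)
    np.fill_diagonal(A, 0.0)
    d = A.sum(1)
    W = A / np.outer(d, d) ** alpha
    dp = W.sum(1)
    P = W / dp[:, None]
    evals, evecs = linalg.eig(P)
    evals = evals.real
    evecs = evecs.real
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    out = []
    pi = dp / dp.sum()
    for i in range(1, min(n_components + 1, len(evals))):
        v = evecs[:, i]
        v = v / np.sqrt(np.sum(pi * v * v))
        out.append(v * evals[i] / (1 - evals[i]))
    emb = np.column_stack(out)
    flip = np.sign(emb[np.abs(emb).argmax(axis=0), np.arange(emb.shape[1])])
    return evals[1 : emb.shape[1] + 1], emb * flip


def block_affinity(n=20, bridge=0.02):
    """Two equal blocks weakly bridged."""
    A = np.full((n, n), bridge)
    h = n // 2
    A[:h, :h] = 1.0
    A[h:, h:] = 1.0
    np.fill_diagonal(A, 0.0)
    return A


def generic_affinity(n, seed=0):
    """Dense symmetric positive affinity with distinct eigenvalues."""
    rng = np.random.default_rng(seed)
    M = rng.uniform(0.05, 1.0, (n, n))
    A = (M + M.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


class TestGroupMean:
    def test_identical_matrices(self, toy_parcellation):
        edges = np.linspace(-0.5, 0.8, toy_parcellation.n_edges)
        fc = pd.DataFrame([edges] * 3, columns=toy_parcellation.edge_labels())
        mean = group_mean_fc(fc, toy_parcellation)
        assert mean.shape == (4, 4)  # cortical only
        np.testing.assert_allclose(np.diag(mean), 1.0)
        np.testing.assert_allclose(mean.to_numpy(), mean.to_numpy().T)

    def test_opposite_matrices_cancel(self, toy_parcellation):
        edges = np.linspace(-0.5, 0.8, toy_parcellation.n_edges)
        fc = pd.DataFrame([edges, -edges], columns=toy_parcellation.edge_labels())
        mean = group_mean_fc(fc, toy_parcellation)
        off = mean.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_elementwise_mean_oracle(self, toy_parcellation, rng):
        fc = pd.DataFrame(
            rng.uniform(-1, 1, (3, toy_parcellation.n_edges)),
            columns=toy_parcellation.edge_labels(),
        )
        mean = group_mean_fc(fc, toy_parcellation, cortical_only=False)
        expected = fc.to_numpy().mean(axis=0)
        np.testing.assert_allclose(matrix_to_edges(mean.to_numpy()), expected)


class TestRowThreshold:
    def test_density_keeps_ceil_entries(self, rng):
        M = rng.standard_normal((11, 11))
        out = row_threshold(M, 0.10)  # ceil(0.1 * 10) = 1 per row
        assert np.all((out != 0).sum(axis=1) == 1)

    def test_ties_at_cutoff_all_kept(self):
        M = np.array(
            [
                [0.0, 5.0, 5.0, 1.0],
                [5.0, 0.0, 1.0, 2.0],
                [1.0, 2.0, 0.0, 3.0],
                [1.0, 2.0, 3.0, 0.0],
            ]
        )
        out = row_threshold(M, 1 / 3)  # keep 1 per row, but row 0 ties
        assert (out[0] != 0).sum() == 2

    def test_matches_sort_enumeration(self, rng):
        M = rng.standard_normal((5, 5))
        out = row_threshold(M, 0.5)  # keep ceil(0.5*4)=2 per row
        for i in range(5):
            offdiag = [(M[i, j], j) for j in range(5) if j != i]
            kept = {j for _, j in sorted(offdiag, reverse=True)[:2]}
            assert {j for j in range(5) if out[i, j] != 0} == kept

    def test_rejects_zero_kept(self):
        # a single-parcel matrix has no off-diagonal entries to keep
        with pytest.raises(ValueError):
            row_threshold(np.ones((1, 1)), 0.5)


class TestCosineAffinity:
    def test_identical_rows_affinity_one(self):
        T = np.tile([1.0, 2.0, 0.0], (3, 1))
        A = cosine_affinity(T)
        np.testing.assert_allclose(A, 1.0)

    def test_orthogonal_rows_affinity_zero(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = cosine_affinity(T)
        assert A[0, 1] == 0.0

    def test_matches_dot_norm_oracle(self, rng):
        T = np.abs(rng.standard_normal((3, 6)))
        A = cosine_affinity(T)
        for i in range(3):
            for j in range(3):
                expected = T[i] @ T[j] / (np.linalg.norm(T[i]) * np.linalg.norm(T[j]))
                np.testing.assert_allclose(A[i, j], max(expected, 0.0), atol=1e-12)

    def test_rejects_zero_row(self):
        T = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            cosine_affinity(T)


class TestDiffusionEmbedding:
    def test_matches_dense_oracle_4x4(self):
        A = np.array(
            [
                [0.0, 0.9, 0.2, 0.1],
                [0.9, 0.0, 0.3, 0.2],
                [0.2, 0.3, 0.0, 0.8],
                [0.1, 0.2, 0.8, 0.0],
            ]
        )
        gs = diffusion_embedding(A, GradientConfig(n_components=3))
        evals, emb = _dense_oracle(A, n_components=3)
        np.testing.assert_allclose(gs.eigenvalues, evals, atol=1e-8)
        np.testing.assert_allclose(gs.embedding.to_numpy(), emb, atol=1e-8)

    def test_matches_dense_oracle_two_block_20(self):
        # a symmetric two-block graph has degenerate eigenvalues whose
        # eigenbasis is arbitrary; jitter breaks the ties so the oracle
        # comparison is exact while the block structure remains dominant
        rng = np.random.default_rng(8)
        A = block_affinity(20)
        J = rng.uniform(0.0, 0.05, (20, 20))
        A = A + (J + J.T) / 2
        np.fill_diagonal(A, 0.0)
        gs = diffusion_embedding(A, GradientConfig(n_components=5))
        evals, emb = _dense_oracle(A, n_components=5)
        np.testing.assert_allclose(gs.eigenvalues, evals, atol=1e-8)
        np.testing.assert_allclose(gs.embedding.to_numpy(), emb, atol=1e-8)

    def test_first_gradient_sign_separates_blocks(self):
        gs = diffusion_embedding(block_affinity(20))
        g1 = gs.embedding.iloc[:, 0].to_numpy()
        assert len(set(np.sign(g1[:10]))) == 1
        assert np.sign(g1[0]) == -np.sign(g1[10])

    def test_parcel_permutation_equivariance(self, rng):
        A = generic_affinity(12, seed=4)
        perm = rng.permutation(12)
        g1 = diffusion_embedding(A, GradientConfig(n_components=3))
        g2 = diffusion_embedding(A[np.ix_(perm, perm)], GradientConfig(n_components=3))
        np.testing.assert_allclose(
            np.abs(g1.embedding.to_numpy()[perm]),
            np.abs(g2.embedding.to_numpy()),
            atol=1e-8,
        )

    def test_scale_invariance_of_affinity(self):
        A = generic_affinity(10, seed=5)
        g1 = diffusion_embedding(A, GradientConfig(n_components=3))
        g2 = diffusion_embedding(3.7 * A, GradientConfig(n_components=3))
        np.testing.assert_allclose(
            g1.embedding.to_numpy(), g2.embedding.to_numpy(), atol=1e-8
        )

    def test_eigenvalue_and_variance_invariants(self):
        gs = diffusion_embedding(block_affinity(16, bridge=0.05))
        assert np.all(gs.eigenvalues < 1 + 1e-10)
        assert np.all(np.diff(gs.eigenvalues) <= 1e-12)
        assert np.all(gs.variance_explained >= 0)
        np.testing.assert_allclose(gs.variance_explained.sum(), 1.0)

    def test_rejects_disconnected_graph(self):
        A = block_affinity(10, bridge=0.0)
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embedding(A)

    def test_rejects_asymmetric(self):
        A = block_affinity(6)
        A[0, 1] += 0.5
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_embedding(A)


class TestProcrustes:
    def _gs(self, rng, n=6, k=2):
        return diffusion_embedding(
            generic_affinity(n, seed=6), GradientConfig(n_components=k)
        )

    def test_self_alignment_is_identity(self, rng):
        gs = self._gs(rng)
        aligned = procrustes_align(gs, gs.embedding.to_numpy())
        np.testing.assert_allclose(aligned.alignment, np.eye(2), atol=1e-10)

    def test_sign_flip_gives_reflection(self, rng):
        gs = self._gs(rng)
        ref = gs.embedding.to_numpy() * np.array([1.0, -1.0])
        aligned = procrustes_align(gs, ref)
        np.testing.assert_allclose(aligned.alignment, np.diag([1.0, -1.0]), atol=1e-8)

    def test_matches_svd_oracle(self, rng):
        G = rng.standard_normal((6, 2))
        ref = rng.standard_normal((6, 2))
        gs = self._gs(rng)
        gs.embedding.iloc[:, :] = G
        aligned = procrustes_align(gs, ref)
        # independent oracle: SVD of GᵀRef gives the optimal rotation
        U, _, Vt = np.linalg.svd(G.T @ ref)
        R = U @ Vt
        np.testing.assert_allclose(aligned.alignment, R, atol=1e-8)
        np.testing.assert_allclose(aligned.embedding.to_numpy(), G @ R, atol=1e-8)

    def test_rejects_shape_mismatch(self, rng):
        gs = self._gs(rng)
        with pytest.raises(ValueError, match="shape"):
            procrustes_align(gs, np.zeros((6, 5)))


def test_planted_axis_recovered_by_first_gradient(small_cohort):
    """The block-model cohort orders networks along a 1-D axis; the first
    gradient of the group-mean FC recovers that ranking."""
    from scipy.stats import spearmanr

    parc = small_cohort.parcellation
    mean = group_mean_fc(small_cohort.modalities["rest_fc"], parc)
    aff = cosine_affinity(row_threshold(mean, 0.10))
    gs = diffusion_embedding(aff, GradientConfig())
    axis = parc.network_axis[parc.network[parc.cortical_mask] - 1]
    rho = spearmanr(gs.embedding.iloc[:, 0].to_numpy(), axis)[0]
    assert abs(rho) >= 0.8
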