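"""Reduction vectors, reduced adjacency, correction matrix, residuals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netreduce import (
    NodePartition,
    WeightedDigraph,
    block_decompose,
    compatibility_residuals,
    correction_matrix,
    decoupled_matrices,
    homogeneous_block_fixture,
    homogeneous_vectors,
    positivize,
    reduce_network,
    reduced_adjacency,
    spectral_vectors,
)
from netreduce.reduction import ReductionVectors, _solve_simplex_quadratic

from conftest import random_grouped_net, random_positive_net


class TestHomogeneousVectors:
    def test_uniform_weights(self):
        part = NodePartition.from_sizes([2, 3])
        vecs = homogeneous_vectors(part)
        assert np.allclose(vecs.partial_vectors[0], [0.5, 0.5])
        assert np.allclose(vecs.partial_vectors[1], [1 / 3] * 3)

    def test_observables_are_group_means(self, rng):
        part = NodePartition.from_sizes([3, 2])
        x = rng.normal(size=5)
        X = homogeneous_vectors(part).observe(part, x)
        assert X == pytest.approx([x[:3].mean(), x[3:].mean()])


class TestDecoupledMatrices:
    def test_single_group_is_transpose(self, small_positive_net):
        blocks = block_decompose(small_positive_net, NodePartition.single_group(8))
        (mat,) = decoupled_matrices(blocks, 0)
        assert np.array_equal(mat, small_positive_net.weights.T)

    def test_scalar_blocks_cross_product(self, rng):
        net = random_positive_net(rng, 2)
        blocks = block_decompose(net, NodePartition.singletons(2))
        mats = decoupled_matrices(blocks, 0)
        # 2-step interaction via the other (singleton) group
        assert mats[1][0, 0] == pytest.approx(net.weights[1, 0] * net.weights[0, 1])

    def test_cross_matrices_have_real_positive_perron_root(self, rng):
        from netreduce.reduction import dominant_eigenvalue

        for _ in range(10):
            net, part = random_grouped_net(rng, [6, 5])
            blocks = block_decompose(net, part)
            for nu in range(2):
                for rho, mat in enumerate(decoupled_matrices(blocks, nu)):
                    lam = dominant_eigenvalue(mat)
                    assert lam > 0
                    # dominant eigenvalue matches a dense eigensolver
                    dense = np.linalg.eigvals(mat)
                    assert lam == pytest.approx(np.abs(dense).max(), rel=1e-10)


class TestSpectralVectors:
    def test_requires_positive_matrix(self):
        net = WeightedDigraph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="positivize"):
            spectral_vectors(net, NodePartition.single_group(2))

    def test_single_group_gives_left_perron_vector(self):
        W = np.array([[1.0, 2.0], [3.0, 4.0]])
        net = WeightedDigraph(W)
        part = NodePartition.single_group(2)
        vecs, report = spectral_vectors(net, part)
        evals, evecs = np.linalg.eig(W.T)
        k = np.argmax(evals.real)
        expected = np.abs(evecs[:, k].real)
        expected /= expected.sum()
        assert np.allclose(vecs.partial_vectors[0], expected, atol=1e-10)
        # reduced coupling equals the spectral radius
        blocks = block_decompose(net, part)
        W11 = reduced_adjacency(blocks, vecs)[0, 0]
        assert W11 == pytest.approx(np.abs(evals).max(), abs=1e-10)
        assert report.lambda_prime[0, 0] == pytest.approx(np.abs(evals).max())

    def test_homogeneous_fixture_recovers_uniform_vectors(self):
        net = homogeneous_block_fixture([3, 4], [[0.7, 0.2], [0.4, 1.1]])
        part = NodePartition.from_sizes([3, 4])
        vecs, report = spectral_vectors(net, part)
        assert np.allclose(vecs.partial_vectors[0], 1 / 3, atol=1e-10)
        assert np.allclose(vecs.partial_vectors[1], 1 / 4, atol=1e-10)
        assert report.residual_adjacency.max() < 1e-10
        assert report.residual_indegree.max() < 1e-10

    def test_singleton_groups_zero_residuals(self, rng):
        net = random_positive_net(rng, 5)
        vecs, report = spectral_vectors(net, NodePartition.singletons(5))
        assert report.residual_adjacency.max() == 0.0
        assert report.residual_indegree.max() == 0.0

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_vectors_live_on_the_simplex(self, seed):
        rng = np.random.default_rng(seed)
        net, part = random_grouped_net(rng, [5, 4, 3])
        vecs, _ = spectral_vectors(net, part)
        for v in vecs.partial_vectors:
            assert v.min() >= 0.0
            assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isolated_nodes_get_vanishing_weight(self):
        """A group mixing one connected node with isolated ones: as the
        positivization weight vanishes, so does the isolated nodes' share."""
        w = np.zeros((6, 6))
        w[0, 4] = 1.0
        w[4, 0] = 2.0
        w[0, 5] = 0.5
        w[5, 0] = 1.5
        w[4, 5] = 1.0
        w[5, 4] = 0.7
        part = NodePartition(np.array([0, 0, 0, 0, 1, 2]))
        prev = None
        for eps in (1e-4, 1e-6, 1e-8):
            net = positivize(WeightedDigraph(w), eps)
            vecs, _ = spectral_vectors(net, part)
            isolated = vecs.partial_vectors[0][1:].max()
            assert isolated < 10 * eps * 6
            if prev is not None:
                assert isolated < prev
            prev = isolated


class TestSimplexSolver:
    def test_beats_random_simplex_points(self, rng):
        for _ in range(10):
            C = rng.normal(size=(6, 6))
            M = C.T @ C
            a = _solve_simplex_quadratic(M)
            obj = a @ M @ a
            samples = rng.dirichlet(np.ones(6), size=500)
            assert obj <= np.einsum("ij,jk,ik->i", samples, M, samples).min() + 1e-10

    def test_activates_nonnegativity_when_needed(self):
        # crafted so the equality-constrained optimum is negative somewhere
        M = np.diag([1.0, 1.0, 0.0]) + np.array(
            [[0.0, 0.0, -2.0], [0.0, 0.0, -2.0], [-2.0, -2.0, 8.0]]
        )
        a = _solve_simplex_quadratic(M)
        assert a.min() >= 0.0
        assert a.sum() == pytest.approx(1.0)


class TestReducedAdjacency:
    def test_homogeneous_fixture_values(self):
        net = homogeneous_block_fixture([2, 3], [[1.0, 2.0], [3.0, 4.0]])
        part = NodePartition.from_sizes([2, 3])
        blocks = block_decompose(net, part)
        W = reduced_adjacency(blocks, homogeneous_vectors(part))
        assert np.allclose(W, [[2.0, 6.0], [6.0, 12.0]])

    def test_singleton_identity(self, rng):
        net = random_positive_net(rng, 4)
        part = NodePartition.singletons(4)
        blocks = block_decompose(net, part)
        W = reduced_adjacency(blocks, homogeneous_vectors(part))
        assert np.allclose(W, net.weights)

    def test_two_formulas_agree(self, rng):
        for _ in range(10):
            net, part = random_grouped_net(rng, [4, 5, 3])
            blocks = block_decompose(net, part)
            raw = [rng.uniform(0.1, 1.0, m) for m in part.group_sizes]
            vecs = ReductionVectors(
                partial_vectors=[v / v.sum() for v in raw], method="homogeneous"
            )
            W = reduced_adjacency(blocks, vecs)
            direct = np.array(
                [
                    [vecs.partial_vectors[nu] @ blocks.blocks[nu][rho] @ np.ones(part.group_sizes[rho])
                     for rho in range(3)]
                    for nu in range(3)
                ]
            )
            assert np.allclose(W, direct, atol=1e-12)


class TestCorrectionMatrix:
    def test_scaled_identity_blocks(self):
        net = homogeneous_block_fixture([3, 2], [[0.5, 1.5], [2.5, 0.1]])
        part = NodePartition.from_sizes([3, 2])
        blocks = block_decompose(net, part)
        vecs = homogeneous_vectors(part)
        mu = correction_matrix(blocks, vecs)
        W = reduced_adjacency(blocks, vecs)
        # K blocks are multiples of the identity here, so mu equals W exactly
        assert np.allclose(mu, W, atol=1e-12)

    def test_rayleigh_quotient_arithmetic(self):
        # diag (1, 2, 3) at the uniform vector: (6/9) / (1/3) = 2
        vecs = ReductionVectors(partial_vectors=[np.full(3, 1 / 3)], method="homogeneous")

        class FakeBlocks:
            n_groups = 1
            indegree = [[np.array([1.0, 2.0, 3.0])]]

        mu = correction_matrix(FakeBlocks(), vecs)
        assert mu[0, 0] == pytest.approx(2.0)

    def test_bounded_by_indegree_extremes(self, rng):
        for _ in range(20):
            net, part = random_grouped_net(rng, [6, 4])
            rsys = reduce_network(net, part, "spectral")
            blocks = block_decompose(net, part)
            for nu in range(2):
                for rho in range(2):
                    k = blocks.indegree[nu][rho]
                    assert k.min() - 1e-12 <= rsys.correction[nu, rho] <= k.max() + 1e-12


class TestResiduals:
    def test_spectral_beats_homogeneous(self, rng):
        """The spectral vector minimizes the residual over the simplex, so the
        homogeneous vector can never do better on the same matrices."""
        for _ in range(10):
            net, part = random_grouped_net(rng, [6, 5, 4])
            vecs, report = spectral_vectors(net, part)
            blocks = block_decompose(net, part)
            hom = compatibility_residuals(
                blocks, homogeneous_vectors(part), report.lambda_prime
            )
            assert (
                report.total_adjacency_residual()
                <= hom.total_adjacency_residual() + 1e-10
            )
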