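"""Message-passing layers against brute-force per-node oracles."""

import numpy as np
import pytest

from mvmwgl.autodiff import constant
from mvmwgl.gnn import (
    GATLayer,
    GCNLayer,
    concat_gene_reps,
    gat_attention_forward,
    gat_forward,
    gcn_forward,
    global_mean_pool,
    mean_pool_forward,
    mlp_forward,
    softmax_forward,
)


def random_graph(rng, n):
    A = (rng.uniform(size=(n, n)) < 0.45).astype(float)
    A = np.triu(A, 1)
    return A + A.T


def gcn_operator(A):
    n = A.shape[0]
    A_hat = A + np.eye(n)
    d = A_hat.sum(axis=1)
    return A_hat / np.sqrt(np.outer(d, d))


def gcn_per_node_oracle(H, A, W):
    """Direct per-node sum over the closed neighborhood with 1/sqrt(di dj)."""
    n = A.shape[0]
    d = A.sum(axis=1) + 1.0  # self-looped degrees
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        acc = np.zeros(H.shape[1])
        for j in range(n):
            if A[i, j] or i == j:
                acc = acc + H[j] / np.sqrt(d[i] * d[j])
        out[i] = np.maximum(acc @ W, 0.0)
    return out


def gat_per_node_oracle(H, A, W, a, slope=0.2):
    """Scalar evaluation of attention scores and weighted aggregation."""
    n = A.shape[0]
    out_dim = W.shape[1]
    WH = H @ W
    out = np.zeros((n, out_dim))
    alpha = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j] or j == i]
        scores = []
        for j in nbrs:
            s = float(a @ np.concatenate([WH[i], WH[j]]))
            scores.append(s if s > 0 else slope * s)
        scores = np.array(scores)
        e = np.exp(scores - scores.max())
        coeff = e / e.sum()
        for j, c in zip(nbrs, coeff):
            alpha[i, j] = c
        out[i] = np.maximum(sum(c * WH[j] for j, c in zip(nbrs, coeff)), 0.0)
    return alpha, out


class TestGCN:
    def test_isolated_node_identity_and_relu(self):
        H = np.array([[-1.0, 2.0]])
        out = gcn_forward(H, np.eye(1), np.eye(2))
        np.testing.assert_allclose(out, [[0.0, 2.0]])

    def test_zero_input_zero_output(self, rng):
        A = random_graph(rng, 5)
        out = gcn_forward(np.zeros((5, 3)), gcn_operator(A), rng.normal(size=(3, 4)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matrix_form_matches_per_node_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            dims = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            A = random_graph(rng, n)
            H = rng.normal(size=(n, dims[0]))
            W = rng.normal(size=dims)
            got = gcn_forward(H, gcn_operator(A), W)
            want = gcn_per_node_oracle(H, A, W)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_layer_class_agrees_with_functional(self, rng):
        A = random_graph(rng, 6)
        layer = GCNLayer(3, 4, rng)
        H = rng.normal(size=(6, 3))
        got = layer.forward(constant(H), gcn_operator(A)).data
        np.testing.assert_allclose(got, gcn_forward(H, gcn_operator(A), layer.W.data), atol=1e-12)

    def test_node_permutation_equivariance(self, rng):
        n = 7
        A = random_graph(rng, n)
        H = rng.normal(size=(n, 3))
        W = rng.normal(size=(3, 5))
        perm = rng.permutation(n)
        out = gcn_forward(H, gcn_operator(A), W)
        out_p = gcn_forward(H[perm], gcn_operator(A[np.ix_(perm, perm)]), W)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestGAT:
    def test_identical_features_give_uniform_attention(self, rng):
        n = 6
        A = random_graph(rng, n)
        H = np.tile(rng.normal(size=3), (n, 1))
        W = rng.normal(size=(3, 4))
        a = rng.normal(size=8)
        alpha = gat_attention_forward(H, A, W, a)
        for i in range(n):
            deg = A[i].sum() + 1
            nbrs = (A[i] > 0) | (np.arange(n) == i)
            np.testing.assert_allclose(alpha[i, nbrs], 1.0 / deg, atol=1e-12)

    def test_rows_sum_to_one_and_positive_on_support(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 10))
            A = random_graph(rng, n)
            H = rng.normal(size=(n, 3))
            alpha = gat_attention_forward(H, A, rng.normal(size=(3, 4)), rng.normal(size=8))
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)
            support = A + np.eye(n) > 0
            assert (alpha[support] > 0).all()
            assert (alpha[~support] == 0).all()

    def test_three_node_path_scalar_oracle(self):
        A = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        H = np.array([[0.5, -1.0], [1.0, 0.3], [-0.2, 0.8]])
        W = np.array([[0.4, -0.1], [0.2, 0.3]])
        a = np.array([0.1, -0.2, 0.3, 0.05])
        alpha_want, out_want = gat_per_node_oracle(H, A, W, a)
        alpha_got = gat_attention_forward(H, A, W, a)
        np.testing.assert_allclose(alpha_got, alpha_want, atol=1e-10)
        np.testing.assert_allclose(gat_forward(H, A, W, a), out_want, atol=1e-10)

    def test_isolated_node_self_attention(self, rng):
        H = rng.normal(size=(1, 3))
        W = rng.normal(size=(3, 2))
        a = rng.normal(size=4)
        alpha = gat_attention_forward(H, np.zeros((1, 1)), W, a)
        assert alpha[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(
            gat_forward(H, np.zeros((1, 1)), W, a), np.maximum(H @ W, 0.0)
        )

    def test_matrix_form_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            in_dim, out_dim = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            A = random_graph(rng, n)
            H = rng.normal(size=(n, in_dim))
            W = rng.normal(size=(in_dim, out_dim))
            a = rng.normal(size=2 * out_dim)
            _, want = gat_per_node_oracle(H, A, W, a)
            np.testing.assert_allclose(gat_forward(H, A, W, a), want, atol=1e-6)

    def test_layer_class_agrees_with_functional(self, rng):
        n = 6
        A = random_graph(rng, n)
        layer = GATLayer(3, 4, rng)
        H = rng.normal(size=(n, 3))
        a = np.concatenate([layer.a_src.data[:, 0], layer.a_dst.data[:, 0]])
        got = layer.forward(constant(H), A + np.eye(n)).data
        np.testing.assert_allclose(got, gat_forward(H, A, layer.W.data, a), atol=1e-10)


class TestPoolingAndHeads:
    def test_pool_constant_rows(self, rng):
        v = rng.normal(size=4)
        np.testing.assert_allclose(mean_pool_forward(np.tile(v, (5, 1))), v)

    def test_pool_hand_value(self):
        np.testing.assert_allclose(
            mean_pool_forward(np.array([[0.0, 2.0], [2.0, 0.0]])), [1.0, 1.0]
        )

    def test_pool_matches_summation_oracle(self, rng):
        H = rng.normal(size=(7, 3))
        want = np.array([sum(H[i, j] for i in range(7)) / 7 for j in range(3)])
        np.testing.assert_allclose(mean_pool_forward(H), want, atol=1e-12)
        np.testing.assert_allclose(global_mean_pool(constant(H)).data, want, atol=1e-12)

    def test_pool_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mean_pool_forward(np.zeros((0, 3)))

    def test_softmax_zero_logits_uniform(self):
        np.testing.assert_allclose(softmax_forward(np.zeros(6)), np.full(6, 1 / 6))

    def test_softmax_shift_invariance(self, rng):
        z = rng.normal(size=5)
        np.testing.assert_allclose(softmax_forward(z), softmax_forward(z + 17.3), atol=1e-12)

    def test_softmax_scalar_oracle(self):
        z = np.array([1.0, 2.0, 3.0])
        want = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(softmax_forward(z), want, atol=1e-12)

    def test_concat_and_block_round_trip(self):
        reps = [np.array([1.0, 2.0]), np.array([3.0, 4.0])]
        H = concat_gene_reps(reps)
        np.testing.assert_array_equal(H, [1, 2, 3, 4])
        np.testing.assert_array_equal(H.reshape(2, 2)[1], reps[1])
        # permuting gene order permutes blocks
        np.testing.assert_array_equal(concat_gene_reps(reps[::-1]), [3, 4, 1, 2])

    def test_concat_inconsistent_dims_rejected(self):
        with pytest.raises(ValueError):
            concat_gene_reps([np.zeros(2), np.zeros(3)])

    def test_mlp_zero_weights_outputs_bias(self):
        W = [np.zeros((3, 2)), np.zeros((2, 1))]
        b = [np.zeros(2), np.array([4.5])]
        assert mlp_forward(np.ones(3), W, b)[0] == pytest.approx(4.5)

    def test_mlp_identity_single_layer(self):
        out = mlp_forward(np.array([7.0]), [np.eye(1)], [np.zeros(1)])
        assert out[0] == pytest.approx(7.0)

    def test_mlp_scalar_oracle(self):
        W = [np.array([[0.5], [-0.25]]), np.array([[2.0]])]
        b = [np.array([0.1]), np.array([-0.3])]
        z = np.array([2.0, 4.0])
        hidden = max(0.5 * 2 - 0.25 * 4 + 0.1, 0.0)
        want = 2.0 * hidden - 0.3
        assert mlp_forward(z, W, b)[0] == pytest.approx(want)
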