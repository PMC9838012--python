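"""Representation learners against explicit-loop reference implementations."""

import numpy as np
import pytest
import scipy.sparse as sp

from mrngcn import _tensor as T
from mrngcn.data_model import degree_normalize
from mrngcn.features import AffineLift
from mrngcn.hgcn import (AttentionParams, HgcnParams, bilinear_aggregate,
                         bilinear_pair_count, hgcn_layer, hgcn_stack,
                         hgcn_stack_bipartite, mix_bilinear,
                         pretrain_gene_mirna, sample_bipartite_negatives,
                         self_attention)
from mrngcn.training import auc_score


def hgcn_layer_oracle(P, X_self, X_nbr, theta, W1, b1, act=lambda x: np.maximum(x, 0)):
    """Per-node double-loop reference for one HGCN layer."""
    n = P.shape[0]
    out = np.zeros((n, theta.shape[1]))
    for v in range(n):
        prop = np.zeros(X_nbr.shape[1])
        for u in range(P.shape[1]):
            prop += P[v, u] * X_nbr[u]
        out[v] = act(prop @ theta + (prop * X_self[v]) @ W1 + b1)
    return out


class TestHgcnLayer:
    def test_zero_adjacency_zero_output(self, rng):
        X = rng.normal(size=(4, 3))
        theta = T.parameter(rng.normal(size=(3, 2)))
        W1 = T.parameter(rng.normal(size=(3, 2)))
        b1 = T.parameter(np.zeros(2))
        out = hgcn_layer(sp.csr_matrix((4, 4)), X, X, theta, W1, b1)
        assert (out.data == 0).all()

    def test_reduces_to_plain_propagation(self, rng):
        # theta = I, W1 = 0, b1 = 0, identity activation -> P @ X
        P = degree_normalize(sp.csr_matrix((rng.random((5, 5)) < 0.4).astype(float)))
        X = rng.normal(size=(5, 3))
        theta = T.parameter(np.eye(3))
        W1 = T.parameter(np.zeros((3, 3)))
        b1 = T.parameter(np.zeros(3))
        out = hgcn_layer(P, X, X, theta, W1, b1, activation=lambda x: x)
        np.testing.assert_allclose(out.data, P.toarray() @ X, atol=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_loop_oracle(self, rng, trial):
        n, m = 7, 5
        P = degree_normalize(sp.csr_matrix((rng.random((n, m)) < 0.4).astype(float)))
        Xs = rng.normal(size=(n, 4))
        Xn = rng.normal(size=(m, 4))
        theta = T.parameter(rng.normal(size=(4, 3)))
        W1 = T.parameter(rng.normal(size=(4, 3)))
        b1 = T.parameter(rng.normal(size=3))
        out = hgcn_layer(P, Xs, Xn, theta, W1, b1)
        expect = hgcn_layer_oracle(P.toarray(), Xs, Xn, theta.data, W1.data,
                                   b1.data)
        np.testing.assert_allclose(out.data, expect, atol=1e-6)

    def test_shape_mismatch_error(self, rng):
        theta = T.parameter(rng.normal(size=(4, 3)))
        W1 = T.parameter(rng.normal(size=(4, 3)))
        b1 = T.parameter(np.zeros(3))
        with pytest.raises(ValueError):
            hgcn_layer(sp.eye(3).tocsr(), rng.normal(size=(3, 2)),
                       rng.normal(size=(3, 2)), theta, W1, b1)


class TestHgcnStack:
    def test_L1_equals_single_layer(self, rng):
        P = degree_normalize(sp.csr_matrix((rng.random((6, 6)) < 0.3).astype(float)))
        X = rng.normal(size=(6, 4))
        params = HgcnParams(4, (3,), rng)
        theta, W1, b1 = params.layers[0]
        one = hgcn_layer(P, X, X, theta, W1, b1)
        stacked = hgcn_stack(P, X, params)
        np.testing.assert_array_equal(one.data, stacked.data)

    def test_output_width_follows_filters(self, rng):
        P = degree_normalize(sp.csr_matrix((rng.random((6, 6)) < 0.3).astype(float)))
        params = HgcnParams(10, (256, 128), rng)
        out = hgcn_stack(P, rng.normal(size=(6, 10)), params)
        assert out.data.shape == (6, 128)

    def test_deterministic_without_dropout(self, rng):
        P = degree_normalize(sp.csr_matrix((rng.random((6, 4)) < 0.4).astype(float)))
        params = HgcnParams(3, (4, 2), np.random.default_rng(0))
        Xa, Xb = rng.normal(size=(6, 3)), rng.normal(size=(4, 3))
        o1 = hgcn_stack_bipartite(P, Xa, Xb, params)
        o2 = hgcn_stack_bipartite(P, Xa, Xb, params)
        np.testing.assert_array_equal(o1[0].data, o2[0].data)
        np.testing.assert_array_equal(o1[1].data, o2[1].data)

    def test_parameter_sharing_gradient_reaches_all_branches(self, rng):
        # one shared theta receives gradient from all three network passes
        params = HgcnParams(3, (2,), np.random.default_rng(1))
        P1 = degree_normalize(sp.csr_matrix(np.ones((4, 4)) - np.eye(4)))
        P2 = degree_normalize(sp.csr_matrix(np.ones((4, 3))))
        P3 = degree_normalize(sp.csr_matrix(np.ones((4, 2))))
        Xg = rng.normal(size=(4, 3))
        loss = hgcn_stack(P1, Xg, params).sum()
        loss = loss + hgcn_stack_bipartite(P2, Xg, rng.normal(size=(3, 3)), params)[0].sum()
        loss = loss + hgcn_stack_bipartite(P3, Xg, rng.normal(size=(2, 3)), params)[0].sum()
        loss.backward()
        theta = params.layers[0][0]
        assert theta.grad is not None and np.abs(theta.grad).sum() > 0


def bilinear_oracle(A, Xg, Xo, W, b):
    """Explicit i<j pair enumeration over each extended neighbourhood."""
    n, m = A.shape
    s_g = Xg @ W + b
    s_o = Xo @ W + b
    out = np.zeros((n, W.shape[1]))
    for p in range(n):
        members = [("g", p)] + [("o", j) for j in range(m) if A[p, j]]
        d = len(members)
        bP = d * (d - 1) / 2
        if bP == 0:
            continue
        acc = np.zeros(W.shape[1])
        for a in range(d):
            for bidx in range(a + 1, d):
                sa = s_g[members[a][1]] if members[a][0] == "g" else s_o[members[a][1]]
                sb = s_g[members[bidx][1]] if members[bidx][0] == "g" else s_o[members[bidx][1]]
                acc += sa * sb
        out[p] = acc / bP
    return out


class TestBilinear:
    def test_pair_count_formula(self):
        for d in range(1, 11):
            assert bilinear_pair_count(d) == d * (d - 1) / 2
        assert bilinear_pair_count(2) == 1 and bilinear_pair_count(1) == 0

    def test_single_neighbour_closed_form(self, rng):
        A = sp.csr_matrix(np.array([[1.0]]))
        Xg, Xo = rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
        W = T.parameter(rng.normal(size=(3, 2)))
        b = T.parameter(rng.normal(size=2))
        out = bilinear_aggregate(A, Xg, Xo, W, b)
        s_g = Xg @ W.data + b.data
        s_o = Xo @ W.data + b.data
        np.testing.assert_allclose(out.data, s_g * s_o, atol=1e-10)

    def test_isolated_gene_zero_by_guard(self, rng):
        A = sp.csr_matrix((2, 3))
        out = bilinear_aggregate(A, rng.normal(size=(2, 3)),
                                 rng.normal(size=(3, 3)),
                                 T.parameter(rng.normal(size=(3, 2))),
                                 T.parameter(rng.normal(size=2)))
        assert (out.data == 0).all()

    @pytest.mark.parametrize("trial", range(5))
    def test_fast_identity_matches_pair_enumeration(self, rng, trial):
        A = (rng.random((6, 8)) < 0.4).astype(float)
        Xg, Xo = rng.normal(size=(6, 4)), rng.normal(size=(8, 4))
        W = T.parameter(rng.normal(size=(4, 3)))
        b = T.parameter(rng.normal(size=3))
        out = bilinear_aggregate(sp.csr_matrix(A), Xg, Xo, W, b)
        expect = bilinear_oracle(A, Xg, Xo, W.data, b.data)
        np.testing.assert_allclose(out.data, expect, atol=1e-6)


class TestMixBilinear:
    def test_alpha_endpoints(self, rng):
        H1, H2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        np.testing.assert_array_equal(mix_bilinear(H1, H2, 0.0).data, H1)
        np.testing.assert_array_equal(mix_bilinear(H1, H2, 1.0).data, H2)

    def test_alpha_out_of_range(self, rng):
        H = rng.normal(size=(2, 2))
        with pytest.raises(ValueError):
            mix_bilinear(H, H, 1.5)

    def test_width_mismatch_uses_lift(self, rng):
        H1, H2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 5))
        lift = AffineLift(5, 3, rng=rng)
        out = mix_bilinear(H1, H2, 0.5, lift=lift)
        assert out.data.shape == (4, 3)
        with pytest.raises(ValueError):
            mix_bilinear(H1, H2, 0.5)


def attention_oracle(H, WQ, WK, WV, d):
    Q, K, V = H @ WQ, H @ WK, H @ WV
    n = H.shape[0]
    out = np.zeros_like(H)
    for i in range(n):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(n)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        out[i] = sum(w[j] * V[j] for j in range(n)) + H[i]
    return out


class TestSelfAttention:
    def test_single_gene_residual_doubling(self, rng):
        params = AttentionParams(3, rng=rng, dropout_rate=0.0)
        params.W_V.data = np.eye(3)
        H = rng.normal(size=(1, 3))
        out = self_attention(H, params)
        np.testing.assert_allclose(out.data, 2 * H, atol=1e-12)

    def test_rows_of_softmax_sum_to_one(self, rng):
        H = T.constant(rng.normal(size=(5, 4)))
        params = AttentionParams(4, rng=rng)
        Q = H.data @ params.W_Q.data
        K = H.data @ params.W_K.data
        logits = Q @ K.T / np.sqrt(params.d)
        p = T.softmax_rows(T.constant(logits)).data
        np.testing.assert_allclose(p.sum(axis=1), np.ones(5), atol=1e-6)

    def test_zero_queries_keys_give_uniform_average(self, rng):
        params = AttentionParams(3, rng=rng, dropout_rate=0.0)
        params.W_Q.data[:] = 0.0
        params.W_K.data[:] = 0.0
        H = rng.normal(size=(6, 3))
        V = H @ params.W_V.data
        expect = np.tile(V.mean(axis=0), (6, 1)) + H
        np.testing.assert_allclose(self_attention(H, params).data, expect,
                                   atol=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_scalar_loop_oracle(self, rng, trial):
        params = AttentionParams(4, d=3, rng=rng, dropout_rate=0.0)
        H = rng.normal(size=(3, 4))
        out = self_attention(H, params)
        expect = attention_oracle(H, params.W_Q.data, params.W_K.data,
                                  params.W_V.data, params.d)
        np.testing.assert_allclose(out.data, expect, atol=1e-6)

    def test_outputs_finite_across_random_trials(self, rng):
        params = AttentionParams(5, rng=rng, dropout_rate=0.0)
        for _ in range(100):
            H = rng.normal(scale=3.0, size=(4, 5))
            assert np.isfinite(self_attention(H, params).data).all()


class TestPretraining:
    def _bipartite(self, rng, n=30, t=10):
        A = sp.csr_matrix((rng.random((n, t)) < 0.25).astype(float))
        P = degree_normalize(A)
        return A, P

    def test_epochs_zero_returns_untrained_forward(self, rng):
        A, P = self._bipartite(rng)
        Xp, Xr = rng.normal(size=(30, 6)), rng.normal(size=(10, 4))
        o1 = pretrain_gene_mirna(A, P, Xp, Xr, epochs=0, seed=3,
                                 hidden_dims=(8, 8))
        o2 = pretrain_gene_mirna(A, P, Xp, Xr, epochs=0, seed=3,
                                 hidden_dims=(8, 8))
        assert o1[0].shape == (30, 6) and o1[1].shape == (10, 6)
        np.testing.assert_array_equal(o1[0], o2[0])

    def test_reconstruction_ranks_edges_above_non_edges(self, rng):
        A, P = self._bipartite(rng)
        Xp, Xr = rng.normal(size=(30, 8)), rng.normal(size=(10, 5))
        XPp, XRp = pretrain_gene_mirna(A, P, Xp, Xr, epochs=100, seed=1,
                                       hidden_dims=(16, 16), lr=0.01)
        ii, jj = A.nonzero()
        pos = (XPp[ii] * XRp[jj]).sum(axis=1)
        neg_pairs = sample_bipartite_negatives(A, len(ii),
                                               np.random.default_rng(2))
        neg = (XPp[neg_pairs[:, 0]] * XRp[neg_pairs[:, 1]]).sum(axis=1)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        assert auc_score(y, np.r_[pos, neg]) >= 0.8

    def test_empty_network_is_error(self, rng):
        A = sp.csr_matrix((5, 3))
        with pytest.raises(ValueError, match="empty"):
            pretrain_gene_mirna(A, A, rng.normal(size=(5, 2)),
                                rng.normal(size=(3, 2)))

    def test_negative_sampler_avoids_edges(self, rng):
        A = sp.csr_matrix((rng.random((6, 4)) < 0.5).astype(float))
        edges = set(zip(*A.nonzero()))
        neg = sample_bipartite_negatives(A, 8, rng)
        assert all((i, j) not in edges for i, j in neg)
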