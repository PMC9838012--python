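"""Attribute assembly: biological rates, topological embeddings, outlying
gene detection, the GIP kernel, and miRNA features."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from mrngcn.features import (AffineLift, OmicsTables, detect_outlying_genes,
                             gene_biological_features,
                             gene_topological_features, gip_kernel,
                             gip_svd_features, lift_features, minmax_normalize,
                             mirna_features, outlying_gene_features,
                             zscores_by_context)


def make_omics(rng, n=10, C=3, S=6, t=5, D=4):
    contexts = [f"c{k}" for k in range(C)]
    return OmicsTables(
        contexts=contexts,
        mutation={c: (rng.random((n, S)) < 0.3).astype(float) for c in contexts},
        methylation_diff=rng.random((n, C)),
        expression_diff=rng.random((n, C)),
        mirna_zscore={c: rng.normal(size=(t, S)) for c in contexts},
        mirna_expression_diff={c: rng.normal(size=(t, S)) for c in contexts},
        mirna_disease=(rng.random((t, D)) < 0.4).astype(float),
    )


class TestGeneBiologicalFeatures:
    @pytest.mark.parametrize("C,expected", [(16, 48), (1, 3), (4, 12)])
    def test_column_count_is_3C(self, rng, C, expected):
        omics = make_omics(rng, C=C)
        assert gene_biological_features(omics).shape == (10, expected)

    def test_minmax_definition(self):
        X = np.array([[0.2], [0.4], [0.6]])
        np.testing.assert_allclose(minmax_normalize(X).ravel(), [0, 0.5, 1])

    def test_constant_column_goes_to_zero(self):
        X = np.array([[1.0, 0.0], [1.0, 2.0]])
        out = minmax_normalize(X)
        assert (out[:, 0] == 0).all()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_minmax_range_property(self, seed):
        X = np.random.default_rng(seed).normal(size=(6, 4))
        out = minmax_normalize(X)
        assert out.min() >= 0 and out.max() <= 1
        assert np.allclose(out.min(axis=0), 0) and np.allclose(out.max(axis=0), 1)


class TestTopologicalFeatures:
    def test_dimension_and_determinism(self, random_binary):
        A = random_binary((20, 20), p=0.2, symmetric=True)
        E1 = gene_topological_features(A, dim=16, seed=5, walk_length=10,
                                       num_walks=3, epochs=1)
        E2 = gene_topological_features(A, dim=16, seed=5, walk_length=10,
                                       num_walks=3, epochs=1)
        assert E1.shape == (20, 16)
        np.testing.assert_array_equal(E1, E2)

    def test_isolated_node_zero_row(self):
        A = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], float))
        E = gene_topological_features(A, dim=4, seed=0, walk_length=5,
                                      num_walks=2, epochs=1)
        assert (E[2] == 0).all()
        assert np.abs(E[:2]).sum() > 0


class TestOutlyingDetection:
    def test_z_formula_hand_case(self):
        # row (10, 10, 10, 30): mean 15, population sd sqrt(75); last z ~ 1.73
        # -> not outlying at 2 but outlying at 1.5
        expr = {"c0": np.array([[10.0, 10, 10, 30]])}
        sigma = np.sqrt(((np.array([10, 10, 10, 30]) - 15.0) ** 2).mean())
        rows, z = detect_outlying_genes(expr, ["c0"], threshold=1.5)
        assert z["c0"][0, -1] == pytest.approx((30 - 15) / sigma)
        assert list(rows) == [0]

    def test_constant_row_never_outlying(self):
        expr = {"c0": np.array([[5.0, 5, 5, 5], [1.0, 2, 3, 40]])}
        rows, z = detect_outlying_genes(expr, ["c0"], threshold=1.0)
        assert (z["c0"][0] == 0).all()
        assert 0 not in rows

    def test_infinite_threshold_empty(self, rng):
        expr = {"c0": rng.normal(size=(6, 5))}
        rows, _ = detect_outlying_genes(expr, ["c0"], threshold=np.inf)
        assert len(rows) == 0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10 ** 6),
           st.floats(min_value=0.5, max_value=3.0))
    def test_threshold_monotonicity(self, seed, thr):
        expr = {"c0": np.random.default_rng(seed).normal(size=(8, 6))}
        low, _ = detect_outlying_genes(expr, ["c0"], threshold=thr)
        high, _ = detect_outlying_genes(expr, ["c0"], threshold=thr + 0.5)
        assert set(high) <= set(low)


class TestOutlyingFeatures:
    def test_width_is_2C(self, rng):
        z = {f"c{k}": rng.normal(size=(7, 5)) for k in range(16)}
        F = outlying_gene_features(z, sorted(z), threshold=2.0)
        assert F.shape == (7, 32)

    def test_frequency_definition(self):
        z = {"c0": np.array([[3.0, -3.0, 0.1, 0.2, 0.1, 0.0, 0.0, 0.0]])}
        F = outlying_gene_features(z, ["c0"], threshold=2.0)
        assert F[0, 1] == pytest.approx(2 / 8)  # outlying in 2 of 8 samples
        assert F[0, 0] == pytest.approx(z["c0"].mean())

    def test_single_context_layout(self, rng):
        z = {"c0": rng.normal(size=(4, 6))}
        assert outlying_gene_features(z, ["c0"]).shape == (4, 2)


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        X = np.array([[1.0, 0, 1], [1.0, 0, 1]])
        K = gip_kernel(X)
        assert K[0, 1] == pytest.approx(1.0)

    def test_hand_computed_two_profiles(self):
        # profiles (1,0) and (0,1): mean squared norm 1 -> gamma 1,
        # squared distance 2 -> K = exp(-2)
        K = gip_kernel(np.array([[1.0, 0], [0.0, 1]]), gamma_prime=1.0)
        assert K[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-9)
        assert K[0, 0] == 1.0 and K[1, 1] == 1.0

    def test_matches_double_loop_oracle(self, rng):
        X = (rng.random((20, 8)) < 0.4).astype(float)
        K = gip_kernel(X)
        gamma = 1.0 / (X ** 2).sum(axis=1).mean()
        for i in range(20):
            for j in range(20):
                expect = np.exp(-gamma * ((X[i] - X[j]) ** 2).sum())
                assert abs(K[i, j] - expect) < 1e-10

    def test_symmetry_and_range(self, rng):
        X = (rng.random((10, 5)) < 0.5).astype(float)
        K = gip_kernel(X)
        np.testing.assert_allclose(K, K.T)
        assert (K > 0).all() and (K <= 1).all()

    def test_all_zero_profiles_identity(self):
        K = gip_kernel(np.zeros((3, 4)))
        np.testing.assert_array_equal(K, np.eye(3))


class TestMirnaFeatures:
    def test_pan_cancer_width(self, rng):
        omics = make_omics(rng, C=16, t=20, D=8)
        A_PR = sp.csr_matrix((rng.random((10, 20)) < 0.3).astype(float))
        K = gip_kernel(omics.mirna_disease)
        F = mirna_features(omics, K, A_PR, sim_dim=16)
        assert F.shape == (20, 16 + 16 + 16 + 1)

    def test_single_cancer_width(self, rng):
        omics = make_omics(rng, C=1, t=6, D=4)
        A_PR = sp.csr_matrix((5, 6))
        F = mirna_features(omics, gip_kernel(omics.mirna_disease), A_PR,
                           sim_dim=1)
        assert F.shape == (6, 4)

    def test_degree_column_is_row_count(self, rng):
        omics = make_omics(rng, C=2, t=4, D=4)
        A = np.zeros((9, 4))
        A[:7, 2] = 1.0
        F = mirna_features(omics, gip_kernel(omics.mirna_disease),
                           sp.csr_matrix(A), sim_dim=2)
        assert F[2, -1] == 7.0

    def test_svd_block_deterministic(self, rng):
        K = gip_kernel((rng.random((8, 5)) < 0.5).astype(float))
        np.testing.assert_array_equal(gip_svd_features(K, 4),
                                      gip_svd_features(K, 4))


class TestAffineLift:
    def test_target_width(self, rng):
        lift, out = lift_features(rng.normal(size=(5, 32)), 64, rng=rng)
        assert out.data.shape == (5, 64)

    def test_zero_params_zero_output(self, rng):
        X = rng.normal(size=(4, 3))
        lift = AffineLift(3, 6, rng=rng)
        lift.W.data[:] = 0.0
        lift.b.data[:] = 0.0
        assert (lift(X).data == 0).all()

    def test_identity_init_square(self, rng):
        X = rng.normal(size=(4, 5))
        lift = AffineLift(5, 5, identity=True)
        np.testing.assert_allclose(lift(X).data, X)

    def test_invalid_target_dim(self):
        with pytest.raises(ValueError):
            AffineLift(3, 0)
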