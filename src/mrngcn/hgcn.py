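"""Heterogeneous graph convolution layers, bilinear aggregation, shared
self-attention, and gene-miRNA pre-training.

A heterogeneous graph convolution (HGCN) layer updates node features by
aggregating both neighbourhood features and neighbourhood *interactions*
(element-wise products between a node's own features and its aggregated
neighbour features)::

    AGG_NF = (P @ X_nbr) @ theta
    AGG_NI = ((P @ X_nbr) * X_self) @ W1 + b1
    H      = sigma(AGG_NF + AGG_NI)

where ``P`` is the degree-normalized adjacency of one of the three
networks.  One parameter set (theta_k, W1_k, b1_k) per layer k is shared
by all three networks; for bipartite networks the layer runs in both
directions (gene side and outlying-gene/miRNA side), alternating roles
between layers.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from . import _tensor as T
from ._tensor import (Adam, Tensor, concat, constant, dropout, glorot, matmul,
                      parameter, relu, sigmoid, softmax_rows, spmm)
from .features import AffineLift

__all__ = [
    "HgcnParams",
    "AttentionParams",
    "hgcn_layer",
    "hgcn_stack",
    "hgcn_stack_bipartite",
    "bilinear_aggregate",
    "mix_bilinear",
    "self_attention",
    "pretrain_gene_mirna",
]


def _as_t(x):
    return x if isinstance(x, Tensor) else constant(np.asarray(x, dtype=np.float64))


class HgcnParams:
    """Per-layer (theta, W1, b1), shared across the three networks."""

    def __init__(self, in_dim, hidden_dims, rng):
        self.layers = []
        d = in_dim
        for h in hidden_dims:
            theta = glorot(rng, (d, h))
            W1 = glorot(rng, (d, h))
            b1 = parameter(np.zeros(h))
            self.layers.append((theta, W1, b1))
            d = h

    @property
    def params(self):
        out = []
        for theta, W1, b1 in self.layers:
            out.extend([theta, W1, b1])
        return out


class AttentionParams:
    """One shared self-attention parameter set serving all three feature
    matrices.  W_V is square so the residual addition is well defined."""

    def __init__(self, feat_dim, d=None, rng=None, dropout_rate=0.2):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d = d if d is not None else feat_dim
        self.W_Q = glorot(rng, (feat_dim, self.d))
        self.W_K = glorot(rng, (feat_dim, self.d))
        self.W_V = glorot(rng, (feat_dim, feat_dim))
        self.dropout_rate = dropout_rate

    @property
    def params(self):
        return [self.W_Q, self.W_K, self.W_V]


def hgcn_layer(P, X_self, X_nbr, theta, W1, b1, activation=relu):
    """One HGCN update for the target side of a network.

    ``activation`` is a hook (default ReLU; pass ``lambda x: x`` for the
    identity in tests).
    """
    X_self, X_nbr = _as_t(X_self), _as_t(X_nbr)
    if X_self.shape[1] != X_nbr.shape[1]:
        raise ValueError("X_self and X_nbr widths must match")
    if X_nbr.shape[1] != theta.shape[0]:
        raise ValueError("feature width does not match layer input width")
    prop = spmm(sp.csr_matrix(P), X_nbr)          # P @ X_nbr
    agg_nf = matmul(prop, theta)
    agg_ni = matmul(prop * X_self, W1) + b1
    return activation(agg_nf + agg_ni)


def hgcn_stack(P, X, params, L=None, dropout_rate=0.0, rng=None,
               training=False, activation=relu):
    """Compose L HGCN layers on a homogeneous (gene-gene) network, with
    dropout between layers during training."""
    layers = params.layers if L is None else params.layers[:L]
    H = _as_t(X)
    for k, (theta, W1, b1) in enumerate(layers):
        H = hgcn_layer(P, H, H, theta, W1, b1, activation=activation)
        if k < len(layers) - 1:
            H = dropout(H, dropout_rate, rng, training)
    return H


def hgcn_stack_bipartite(P_ab, X_a, X_b, params, L=None, dropout_rate=0.0,
                         rng=None, training=False, activation=relu):
    """Compose L HGCN layers on a bipartite network: at every layer the
    a-side update aggregates b-side features through P_ab and vice versa
    through its transpose, so the two sides alternate roles between
    layers.  Returns (a-side, b-side) features."""
    P_ab = sp.csr_matrix(P_ab)
    P_ba = P_ab.T.tocsr()
    layers = params.layers if L is None else params.layers[:L]
    Ha, Hb = _as_t(X_a), _as_t(X_b)
    for k, (theta, W1, b1) in enumerate(layers):
        Ha_new = hgcn_layer(P_ab, Ha, Hb, theta, W1, b1, activation=activation)
        Hb_new = hgcn_layer(P_ba, Hb, Ha, theta, W1, b1, activation=activation)
        Ha, Hb = Ha_new, Hb_new
        if k < len(layers) - 1:
            Ha = dropout(Ha, dropout_rate, rng, training)
            Hb = dropout(Hb, dropout_rate, rng, training)
    return Ha, Hb


def bilinear_pair_count(d_tilde):
    """Number of unordered neighbour interactions for extended-neighbourhood
    size d_tilde: b_P = d_tilde * (d_tilde - 1) / 2."""
    d_tilde = np.asarray(d_tilde, dtype=np.float64)
    return d_tilde * (d_tilde - 1.0) / 2.0


def bilinear_aggregate(A_PO, X_gene, X_other, W, b):
    """Bilinear (pairwise-interaction) aggregation over each gene's
    extended neighbourhood (its outlying-gene neighbours plus itself),
    ignoring self-interactions:

        out_p = (1 / b_P) * sum_{i<j in N~(p)} s_i * s_j,   s_i = X(i) @ W + b

    computed by the identity  sum_{i<j} s_i s_j = ((sum s)^2 - sum s^2) / 2.
    Genes with d_tilde <= 1 (no neighbours: a single-element neighbourhood
    has no pairs) get a zero row.
    """
    A = sp.csr_matrix(A_PO)
    Xg, Xo = _as_t(X_gene), _as_t(X_other)
    s_g = matmul(Xg, W) + b
    s_o = matmul(Xo, W) + b
    ssum = s_g + spmm(A, s_o)
    ssq = s_g * s_g + spmm(A, s_o * s_o)
    deg = np.asarray(A.sum(axis=1)).ravel()
    b_P = bilinear_pair_count(deg + 1.0)
    inv = np.where(b_P > 0, 1.0 / np.where(b_P > 0, b_P, 1.0), 0.0)
    return (ssum * ssum - ssq) * constant(0.5 * inv[:, None])


def mix_bilinear(H_P2, H_BA, alpha, lift=None):
    """Convex combination (1 - alpha) * H_P2 + alpha * H_BA; when widths
    differ, H_BA first passes the provided learnable lift."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    H_P2, H_BA = _as_t(H_P2), _as_t(H_BA)
    if H_BA.shape[1] != H_P2.shape[1]:
        if lift is None:
            raise ValueError("width mismatch and no lift provided")
        H_BA = lift(H_BA)
    return constant(1.0 - alpha) * H_P2 + constant(alpha) * H_BA


def self_attention(H, params, rng=None, training=False):
    """Scaled dot-product self-attention with a residual connection:

        out = softmax(Q K^T / sqrt(d)) V + H

    One call per network's gene features, always with the same shared
    parameter set.  Dropout (rate ``params.dropout_rate``) is applied to
    the attention weights during training.
    """
    H = _as_t(H)
    Q = matmul(H, params.W_Q)
    K = matmul(H, params.W_K)
    V = matmul(H, params.W_V)
    scores = matmul(Q, K.T) * constant(1.0 / np.sqrt(params.d))
    attn = softmax_rows(scores)
    attn = dropout(attn, params.dropout_rate, rng, training)
    return matmul(attn, V) + H


# ---------------------------------------------------------------------------
# gene-miRNA pre-training
# ---------------------------------------------------------------------------

def sample_bipartite_negatives(A, size, rng):
    """Uniformly sample ``size`` (row, col) non-edges of a sparse bipartite
    adjacency by rejection."""
    A = sp.csr_matrix(A)
    n, t = A.shape
    if A.nnz >= n * t:
        raise ValueError("graph is complete; no negative pairs exist")
    edges = set(zip(*A.nonzero()))
    out = []
    while len(out) < size:
        i = int(rng.integers(n))
        j = int(rng.integers(t))
        if (i, j) not in edges:
            out.append((i, j))
    return np.array(out, dtype=np.intp)


class PretrainModel:
    """Standalone two-layer HGCN on the gene-miRNA network, trained to
    reconstruct A_PR by inner-product link prediction with 1:1 negative
    sampling; its final-layer features are lifted back to width F1."""

    def __init__(self, A_PR, P_PR, X_P, X_R_const, hidden_dims, seed,
                 gip=None, sim_dim=16, sim_insert=None):
        self.A_PR = sp.csr_matrix(A_PR)
        self.P_PR = sp.csr_matrix(P_PR)
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.X_P = np.asarray(X_P, dtype=np.float64)
        F1 = self.X_P.shape[1]
        self.gip = gip
        self.sim_insert = sim_insert
        if gip is not None:
            self.gip_lift = AffineLift(gip.shape[0], sim_dim, rng=rng)
            F3 = X_R_const.shape[1] + sim_dim
        else:
            self.gip_lift = None
            F3 = X_R_const.shape[1]
        self.X_R_const = np.asarray(X_R_const, dtype=np.float64)
        self.lift_R = AffineLift(F3, F1, rng=rng)
        self.hgcn = HgcnParams(F1, hidden_dims, rng)
        self.out_lift_P = AffineLift(hidden_dims[-1], F1, rng=rng)
        self.out_lift_R = AffineLift(hidden_dims[-1], F1, rng=rng)

    @property
    def params(self):
        out = self.lift_R.params + self.hgcn.params
        out += self.out_lift_P.params + self.out_lift_R.params
        if self.gip_lift is not None:
            out += self.gip_lift.params
        return out

    def _X_R(self):
        if self.gip_lift is None:
            return constant(self.X_R_const)
        sim = self.gip_lift(constant(self.gip))
        k = self.sim_insert if self.sim_insert is not None else self.X_R_const.shape[1]
        left = constant(self.X_R_const[:, :k])
        right = constant(self.X_R_const[:, k:])
        parts = [p for p in (left, sim, right) if p.shape[1] > 0]
        return concat(parts, axis=1)

    def forward(self):
        XR = self.lift_R(self._X_R())
        G, R = hgcn_stack_bipartite(self.P_PR, constant(self.X_P), XR, self.hgcn)
        return self.out_lift_P(G), self.out_lift_R(R)

    def link_loss(self, Xp, Xr, neg):
        ii, jj = self.A_PR.nonzero()
        pos_logit = (T.take_rows(Xp, ii) * T.take_rows(Xr, jj)).sum(axis=1)
        neg_logit = (T.take_rows(Xp, neg[:, 0]) * T.take_rows(Xr, neg[:, 1])).sum(axis=1)
        pos = T.clamp(sigmoid(pos_logit), 1e-7, 1 - 1e-7)
        negp = T.clamp(sigmoid(neg_logit), 1e-7, 1 - 1e-7)
        n_e = float(len(ii))
        return (-T.log(pos).sum() - T.log(constant(1.0) - negp).sum()) * constant(1.0 / n_e)


def pretrain_gene_mirna(A_PR, P_PR, X_P, X_R, epochs=100, seed=0,
                        hidden_dims=(256, 128), lr=0.01, gip=None,
                        sim_dim=16, sim_insert=None):
    """Pre-train on the gene-miRNA network; returns (X_P_pre, X_R_pre) as
    plain arrays of width F1.  ``epochs=0`` returns the lift of the
    untrained forward pass.  Deterministic for a fixed seed.

    When ``gip`` is given, the miRNA similarity block is a trainable affine
    reduction of the GIP matrix inserted at column ``sim_insert`` of
    ``X_R`` (which then carries only the fixed columns).
    """
    if sp.csr_matrix(A_PR).nnz == 0:
        raise ValueError("gene-miRNA network is empty; nothing to pre-train on")
    model = PretrainModel(A_PR, P_PR, X_P, X_R, hidden_dims, seed,
                          gip=gip, sim_dim=sim_dim, sim_insert=sim_insert)
    opt = Adam(model.params, lr=lr, weight_decay=5e-4)
    n_edges = model.A_PR.nnz
    for _ in range(epochs):
        neg = sample_bipartite_negatives(model.A_PR, n_edges, model.rng)
        Xp, Xr = model.forward()
        loss = model.link_loss(Xp, Xr, neg)
        opt.zero_grad()
        loss.backward()
        opt.step()
    Xp, Xr = model.forward()
    # the link objective rewards large feature norms; rescale each matrix to
    # unit RMS so the pre-trained features enter the main model (whose
    # interaction terms are quadratic in feature scale) on a sane scale
    def _unit_rms(X):
        rms = np.sqrt((X ** 2).mean())
        return X / rms if rms > 0 else X

    return _unit_rms(Xp.data.copy()), _unit_rms(Xr.data.copy())
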