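"""Assembly of initial node attributes for genes, outlying genes and miRNAs.

Gene attributes concatenate per-cancer-context biological rates (mutation,
differential methylation, differential expression — min-max normalized per
column) with a topological embedding of the gene-gene network.  With C
contexts the biological block has 3C columns (48 pan-cancer with C = 16;
3 single-cancer) and the embedding adds ``dim`` more (default 16, giving
the 64-dimensional pan-cancer gene attributes).

Outlying-gene attributes are per-context mean expression z-scores plus the
per-context frequency of being outlying (|z| above threshold), 2C columns.

miRNA attributes are per-context mean z-scores and mean differential
expression, a similarity block derived from the Gaussian Interaction
Profile (GIP) kernel over miRNA-disease association profiles, and the
miRNA's degree in the gene-miRNA network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _tensor as T
from .embedding import node_embedding

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsTables",
    "minmax_normalize",
    "gene_biological_features",
    "gene_topological_features",
    "detect_outlying_genes",
    "outlying_gene_features",
    "gip_kernel",
    "gip_svd_features",
    "mirna_context_features",
    "mirna_features",
    "AffineLift",
    "lift_features",
]


@dataclass
class OmicsTables:
    """Per-context omics inputs over closed node universes.

    ``mutation`` and ``expression`` map context name -> (nodes x samples)
    arrays; ``methylation_diff`` and ``expression_diff`` are precomputed
    per-context rate columns (nodes x C) — their upstream derivation from
    raw tumor/normal data is delegated to the input tables.
    """

    contexts: list
    mutation: dict = field(default_factory=dict)          # ctx -> n x S binary/count
    methylation_diff: np.ndarray = None                   # n x C
    expression_diff: np.ndarray = None                    # n x C
    expression: dict = field(default_factory=dict)        # ctx -> genes x S (tumor)
    mirna_zscore: dict = field(default_factory=dict)      # ctx -> t x S
    mirna_expression_diff: dict = field(default_factory=dict)  # ctx -> t x S
    mirna_disease: np.ndarray = None                      # t x D binary

    @property
    def C(self):
        return len(self.contexts)


def minmax_normalize(X):
    """Column-wise min-max to [0, 1]; constant columns map to all zeros."""
    X = np.asarray(X, dtype=np.float64)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.info("min-max: %d constant column(s) normalized to zeros",
                    int(const.sum()))
    span = np.where(const, 1.0, span)
    out = (X - lo) / span
    out[:, const] = 0.0
    return out


def gene_biological_features(omics):
    """n x 3C matrix: [mutation rate | methylation | differential expression]
    blocks, each ordered by context and min-max normalized per column."""
    C = omics.C
    mut_cols = []
    for ctx in omics.contexts:
        m = np.asarray(omics.mutation[ctx])
        mut_cols.append((m > 0).mean(axis=1))
    mut = np.column_stack(mut_cols)
    meth = np.asarray(omics.methylation_diff, dtype=np.float64)
    de = np.asarray(omics.expression_diff, dtype=np.float64)
    if meth.shape[1] != C or de.shape[1] != C:
        raise ValueError("methylation/expression blocks must have C columns")
    return minmax_normalize(np.column_stack([mut, meth, de]))


def gene_topological_features(A_PP, dim=16, seed=0, **walk_kwargs):
    """Embedding of the gene-gene network (walks + skip-gram); isolated
    genes receive zero rows.  Deterministic for a fixed seed."""
    A = sp.csr_matrix(A_PP)
    if (A != A.T).nnz:
        raise ValueError("A_PP must be symmetric")
    return node_embedding(A, dim=dim, seed=seed, **walk_kwargs)


def zscores_by_context(expression, contexts):
    """Per-context population z-scores across that context's samples.

    Zero-variance genes get z = 0 in that context (never outlying there).
    """
    out = {}
    for ctx in contexts:
        X = np.asarray(expression[ctx], dtype=np.float64)
        if X.shape[1] < 2:
            raise ValueError(f"context {ctx!r} needs >= 2 samples for z-scores")
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)  # population sd
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (X - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        out[ctx] = z
    return out


def detect_outlying_genes(expression, contexts, threshold=2.0):
    """Identify outlying genes: |z| > threshold in at least one sample of
    any context.  Returns (row positions of outlying genes, z-score dict)."""
    z = zscores_by_context(expression, contexts)
    any_out = np.zeros(next(iter(z.values())).shape[0], dtype=bool)
    for ctx in contexts:
        any_out |= (np.abs(z[ctx]) > threshold).any(axis=1)
    return np.flatnonzero(any_out), z


def outlying_gene_features(zscores, contexts, threshold=2.0, rows=None):
    """m x 2C matrix: per context the mean z-score across all samples and
    the fraction of samples with |z| above the threshold."""
    meanz, freq = [], []
    for ctx in contexts:
        z = np.asarray(zscores[ctx], dtype=np.float64)
        if rows is not None:
            z = z[rows]
        meanz.append(z.mean(axis=1))
        freq.append((np.abs(z) > threshold).mean(axis=1))
    return np.column_stack(meanz + freq)


def gip_kernel(profiles, gamma_prime=1.0):
    """Gaussian Interaction Profile kernel over binary association profiles.

    K[i,j] = exp(-gamma * ||x_i - x_j||^2) with the bandwidth scaled by the
    data: gamma = gamma_prime / mean_i ||x_i||^2.  Symmetric, unit diagonal.
    An all-zero profile matrix leaves gamma undefined; the identity matrix
    is returned (and logged) in that case.
    """
    X = np.asarray(profiles, dtype=np.float64)
    t = X.shape[0]
    if t < 1:
        raise ValueError("need at least one profile")
    sq = (X ** 2).sum(axis=1)
    denom = sq.mean()
    if denom == 0:
        logger.warning("GIP: all profiles empty; returning identity")
        return np.eye(t)
    gamma = gamma_prime / denom
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return K


def gip_svd_features(K, dim=16):
    """Fixed, deterministic reduction of the GIP matrix to ``dim`` columns
    via truncated SVD (K is symmetric PSD, so this is an eigen-embedding
    U_d * sqrt(s_d)); sign convention: largest-magnitude entry of each
    singular vector is made positive."""
    K = np.asarray(K, dtype=np.float64)
    t = K.shape[0]
    dim = min(dim, t)
    U, s, _ = np.linalg.svd(K, hermitian=True)
    U = U[:, :dim]
    for j in range(dim):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
    F = U * np.sqrt(s[:dim])
    if F.shape[1] < dim:
        F = np.pad(F, ((0, 0), (0, dim - F.shape[1])))
    return F


def mirna_context_features(omics):
    """(t x C mean z-score, t x C mean differential expression)."""
    mz = np.column_stack([np.asarray(omics.mirna_zscore[c]).mean(axis=1)
                          for c in omics.contexts])
    md = np.column_stack([np.asarray(omics.mirna_expression_diff[c]).mean(axis=1)
                          for c in omics.contexts])
    return mz, md


def mirna_features(omics, gip, A_PR, sim_dim=16, sim_block=None):
    """t x F3 miRNA attribute matrix:
    [mean z (C) | mean diff-expr (C) | similarity (sim_dim) | degree (1)].

    ``sim_block`` overrides the similarity columns (used when the caller
    owns a trainable transform of the GIP matrix); otherwise the fixed
    truncated-SVD reduction is used.
    """
    mz, md = mirna_context_features(omics)
    if sim_block is None:
        sim_block = gip_svd_features(gip, dim=sim_dim)
    degree = np.asarray(sp.csr_matrix(A_PR).sum(axis=0)).ravel()[:, None]
    return np.column_stack([mz, md, sim_block, degree])


class AffineLift:
    """A learnable affine map X -> X @ W + b to a common feature width.

    Parameters are autodiff tensors registered with (and trained jointly
    by) whichever model owns the lift.
    """

    def __init__(self, in_dim, out_dim, rng=None, identity=False):
        if out_dim < 1:
            raise ValueError("target dimension must be >= 1")
        if identity:
            if in_dim != out_dim:
                raise ValueError("identity init needs a square lift")
            W = np.eye(in_dim)
        else:
            rng = rng if rng is not None else np.random.default_rng(0)
            limit = np.sqrt(6.0 / (in_dim + out_dim))
            W = rng.uniform(-limit, limit, size=(in_dim, out_dim))
        self.W = T.parameter(W)
        self.b = T.parameter(np.zeros(out_dim))

    @property
    def params(self):
        return [self.W, self.b]

    def __call__(self, X):
        X = X if isinstance(X, T.Tensor) else T.constant(X)
        return T.matmul(X, self.W) + self.b


def lift_features(X, target_dim, rng=None, identity=False):
    """Build an :class:`AffineLift` for X and apply it.

    Returns (lift, lifted) so the caller can register the lift's
    parameters for joint training.
    """
    X = np.asarray(X) if not isinstance(X, T.Tensor) else X
    in_dim = X.shape[1]
    lift = AffineLift(in_dim, target_dim, rng=rng, identity=identity)
    return lift, lift(X)
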