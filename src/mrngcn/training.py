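"""Losses, negative sampling, evaluation metrics, and run orchestration.

The multi-task objective combines two node-prediction binary
cross-entropies with an auxiliary link-prediction loss on the gene-gene
network::

    L_total = L_n_loss + omega1 * L_n_loss1 + omega2 * L_r_loss

L_n_loss scores sigmoid(H_syn), L_n_loss1 scores sigmoid(H_2D) (both over
labelled training genes only), and L_r_loss reconstructs gene-gene edges
from the branch-1 1D features by an inner-product decoder against an
equal number of sampled non-edges, resampled every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from . import _tensor as T
from ._tensor import Tensor, constant, sigmoid

__all__ = [
    "node_bce",
    "link_reconstruction",
    "link_bce",
    "total_loss",
    "sample_negative_edges",
    "edge_set",
    "evaluate",
    "auc_score",
    "auprc_score",
    "CvResult",
    "train",
    "cross_validate",
    "ablate",
    "ABLATION_VARIANTS",
]

_EPS = 1e-7


def _as_t(x):
    return x if isinstance(x, Tensor) else constant(np.asarray(x, dtype=np.float64))


def node_bce(scores, labels):
    """Mean binary cross-entropy over labelled genes; scores are clamped
    to [1e-7, 1 - 1e-7] before the logs."""
    scores = _as_t(scores)
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    if y.size == 0:
        raise ValueError("empty label set")
    s = T.clamp(scores, _EPS, 1.0 - _EPS)
    yt = constant(y.reshape(s.data.shape))
    ll = yt * T.log(s) + (constant(1.0) - yt) * T.log(constant(1.0) - s)
    return -ll.sum() * constant(1.0 / y.size)


def link_reconstruction(H, pairs):
    """Reconstructed adjacency entries a_hat_ij = sigmoid(<h_i, h_j>) for
    the requested (i, j) pairs only — the full n x n matrix is never
    materialized."""
    H = _as_t(H)
    pairs = np.asarray(pairs, dtype=np.intp)
    hi = T.take_rows(H, pairs[:, 0])
    hj = T.take_rows(H, pairs[:, 1])
    return sigmoid((hi * hj).sum(axis=1))


def edge_set(A_PP):
    """Unordered gene-gene edges as an (|E|, 2) array with i < j."""
    A = sp.csr_matrix(A_PP)
    ii, jj = sp.triu(A, k=1).nonzero()
    return np.column_stack([ii, jj]).astype(np.intp)


def sample_negative_edges(A_PP, size, rng):
    """Uniformly sample ``size`` unordered non-edges (i < j, A[i,j] = 0)
    by rejection; never returns an existing edge or a self pair."""
    A = sp.csr_matrix(A_PP)
    n = A.shape[0]
    n_pairs = n * (n - 1) // 2
    n_edges = sp.triu(A, k=1).nnz
    if n_pairs - n_edges < size:
        raise ValueError("graph too dense: fewer non-edges than requested")
    edges = set(map(tuple, edge_set(A)))
    out = []
    while len(out) < size:
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i == j:
            continue
        if i > j:
            i, j = j, i
        if (i, j) not in edges:
            out.append((i, j))
    return np.array(out, dtype=np.intp)


def link_bce(E, Neg, H):
    """Link-prediction BCE: -(1/|E|) [sum_E log a_hat + sum_Neg log(1 - a_hat)]."""
    a_pos = T.clamp(link_reconstruction(H, E), _EPS, 1.0 - _EPS)
    a_neg = T.clamp(link_reconstruction(H, Neg), _EPS, 1.0 - _EPS)
    n_e = float(len(E))
    return (-T.log(a_pos).sum() - T.log(constant(1.0) - a_neg).sum()) * constant(1.0 / n_e)


def total_loss(l_node, l_node1, l_link, omega1=0.1, omega2=0.01):
    l_node, l_node1 = _as_t(l_node), _as_t(l_node1)
    l_link = _as_t(l_link) if l_link is not None else constant(0.0)
    return l_node + constant(omega1) * l_node1 + constant(omega2) * l_link


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_score(labels, scores):
    """Mann-Whitney AUC with half credit for tied positive/negative pairs."""
    y = np.asarray(labels).astype(bool).reshape(-1)
    s = np.asarray(scores, dtype=float).reshape(-1)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(s)  # average ranks handle ties with 0.5 credit
    return (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc_score(labels, scores):
    """Average precision by step-wise summation (no interpolation), with
    score ties grouped at a single threshold."""
    y = np.asarray(labels).astype(int).reshape(-1)
    s = np.asarray(scores, dtype=float).reshape(-1)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("AUPRC needs both classes")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    boundaries = np.flatnonzero(np.diff(s)) if y.size > 1 else np.array([], dtype=int)
    idx = np.append(boundaries, y.size - 1)  # last index of each score group
    tp = np.cumsum(y)[idx].astype(float)
    fp = np.cumsum(1 - y)[idx].astype(float)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev) * precision).sum())


def evaluate(scores, labels):
    """(AUC, AUPRC) for a labelled score vector."""
    return auc_score(labels, scores), auprc_score(labels, scores)


@dataclass
class CvResult:
    """Per-fold cross-validation metrics plus out-of-fold gene scores."""

    fold_auc: list
    fold_auprc: list
    oof_scores: dict                 # gene id -> out-of-fold score
    lr_weights: list = field(default_factory=list)   # per fold
    feature_names: list = field(default_factory=list)

    @property
    def mean_auc(self):
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self):
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def mean_auprc(self):
        return float(np.mean(self.fold_auprc))

    @property
    def sd_auprc(self):
        return float(np.std(self.fold_auprc, ddof=1)) if len(self.fold_auprc) > 1 else 0.0

    def summary(self):
        k = len(self.fold_auc)
        lines = [
            f"{k}-fold cross-validation",
            f"  AUC   {self.mean_auc:.4f} +/- {self.sd_auc:.4f} (sd across folds)",
            f"  AUPRC {self.mean_auprc:.4f} +/- {self.sd_auprc:.4f} (sd across folds)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# orchestration (thin wrappers over the model object)
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = {
    "full": {},
    "genes_only": {"use_outlying": False, "use_mirna": False},
    "outlying_only": {"use_gene_gene": False, "use_mirna": False},
    "mirna_only": {"use_gene_gene": False, "use_outlying": False},
    "gene_gene_outlying": {"use_mirna": False},
    "gene_gene_mirna": {"use_outlying": False},
    "outlying_mirna": {"use_gene_gene": False},
    "no_pretrain": {"use_pretrain": False},
    "no_bilinear": {"use_bilinear": False},
    "no_attention": {"use_attention": False},
    "sigmoid_sum": {"combiner": "sigmoid_sum"},
}


def train(networks, attributes, labels, config, gene_ids=None):
    """Train the full model on all labelled genes; returns the fitted
    results object (trained parameters + every intermediate feature)."""
    from .model import MRNGCN

    return MRNGCN(networks, attributes, labels, config=config,
                  gene_ids=gene_ids).fit()


def cross_validate(networks, attributes, labels, config, gene_ids=None):
    from .model import MRNGCN

    return MRNGCN(networks, attributes, labels, config=config,
                  gene_ids=gene_ids).cross_validate()


def ablate(networks, attributes, labels, config, variant, gene_ids=None):
    """Run cross-validation for a named ablation variant."""
    from dataclasses import replace

    from .model import MRNGCN

    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: "
                         f"{sorted(ABLATION_VARIANTS)}")
    cfg = replace(config, **ABLATION_VARIANTS[variant])
    return MRNGCN(networks, attributes, labels, config=cfg,
                  gene_ids=gene_ids).cross_validate()
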