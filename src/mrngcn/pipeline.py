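"""Attribute assembly: from raw omics tables to the model's initial
feature matrices.

Gene attributes X_P = [3C min-max-normalized biological rate columns |
16-d topological embedding of the gene-gene network]; outlying-gene
attributes X_O = [C mean z-scores | C outlying frequencies]; miRNA
attributes X_R = [C mean z-scores | C mean differential expression |
GIP-derived similarity block | degree].

With ``gip_transform='svd'`` the similarity block is a fixed truncated-SVD
reduction of the GIP kernel and X_R is a plain matrix; with ``'affine'``
the block is a trainable reduction owned by whichever model consumes X_R,
so X_R carries only the fixed columns plus the kernel itself
(``AttributeSet.gip`` / ``sim_insert``).
"""

from __future__ import annotations

from .data_model import AttributeSet, RunConfig
from .features import (gene_biological_features, gene_topological_features,
                       gip_kernel, mirna_context_features, mirna_features,
                       outlying_gene_features)

import numpy as np
import scipy.sparse as sp

__all__ = ["assemble_attributes"]


def assemble_attributes(dataset, config: RunConfig = None,
                        topo_dim=16, outlier_threshold=2.0) -> AttributeSet:
    """Build the :class:`AttributeSet` for a synthetic (or equivalently
    structured) dataset.  The topological embedding is seeded from the
    dataset's own seed, so attributes are a property of the dataset, not
    of the training run."""
    cfg = config if config is not None else RunConfig()
    omics = dataset.omics
    net = dataset.networks

    bio = gene_biological_features(omics)
    topo = gene_topological_features(net.A_PP, dim=topo_dim,
                                     seed=dataset.config.seed)
    X_P = np.column_stack([bio, topo])

    X_O = outlying_gene_features(dataset.outlying_zscores, omics.contexts,
                                 threshold=outlier_threshold)

    K = gip_kernel(omics.mirna_disease)
    if cfg.gip_transform == "svd":
        X_R = mirna_features(omics, K, net.A_PR, sim_dim=cfg.gip_dim)
        return AttributeSet(X_P=X_P, X_O=X_O, X_R=X_R)
    # trainable similarity block: X_R holds only the fixed columns, the
    # kernel rides along and the consumer inserts its affine reduction
    mz, md = mirna_context_features(omics)
    degree = np.asarray(sp.csr_matrix(net.A_PR).sum(axis=0)).ravel()[:, None]
    X_R = np.column_stack([mz, md, degree])
    return AttributeSet(X_P=X_P, X_O=X_O, X_R=X_R, gip=K,
                        sim_insert=2 * omics.C)
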