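"""Construction of the three gene relationship networks.

The gene-gene network comes from a (pre-filtered) PPI edge list; the
gene-outlying-gene network links a gene to an outlying gene when the gene is
mutated in at least one sample AND the pair is a PPI edge; the gene-miRNA
network is the indexed restriction of a target-association edge list.
Outlying genes that are also regular genes keep two separate node
identities — the node sets play disjoint roles.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .data_model import NetworkBundle, degree_normalize

logger = logging.getLogger(__name__)

__all__ = ["build_gene_gene", "build_gene_outlying", "build_gene_mirna",
           "normalize", "NetworkBundle"]

# the +1-shifted symmetric degree normalization lives in data_model so the
# container can build its own P matrices; re-exported here as the public op
normalize = degree_normalize


def build_gene_gene(ppi_edges, gene_index):
    """Binary symmetric gene-gene adjacency from an iterable of id pairs.

    Interaction-score filtering (the published pipeline kept score > 0.5)
    is assumed done upstream of the edge list.  Self loops are dropped.
    """
    n = gene_index.n
    rows, cols = [], []
    for a, b in ppi_edges:
        i, j = gene_index.position(a), gene_index.position(b)
        if i == j:
            logger.warning("dropping self-loop on %s", a)
            continue
        rows.extend((i, j))
        cols.extend((j, i))
    if not rows:
        return sp.csr_matrix((n, n))
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A.data[:] = 1.0
    return A


def build_gene_outlying(mutated_mask, outlying_index, ppi_links, gene_index):
    """A_PO[g, o] = 1 iff gene g is mutated in >= 1 sample and (g, o) is a
    PPI link.

    ``ppi_links`` is an iterable of (gene_id, outlying_gene_id) pairs giving
    the PPI incidence between the gene universe and the outlying-gene
    universe (an outlying gene is addressed by its own id even when the same
    symbol also names a regular gene).
    """
    mutated_mask = np.asarray(mutated_mask).astype(bool)
    if mutated_mask.shape[0] != gene_index.n:
        raise ValueError("mutated_mask length must equal gene count")
    rows, cols = [], []
    for g, o in ppi_links:
        i = gene_index.position(g)
        j = outlying_index.position(o)
        if mutated_mask[i]:
            rows.append(i)
            cols.append(j)
    shape = (gene_index.n, outlying_index.n)
    if not rows:
        return sp.csr_matrix(shape)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=shape).tocsr()
    A.data[:] = 1.0
    return A


def build_gene_mirna(target_edges, gene_index, mirna_index):
    """Bipartite gene-miRNA adjacency restricted to the closed indices;
    associations naming unindexed nodes are skipped with a warning."""
    rows, cols = [], []
    for g, r in target_edges:
        if g not in gene_index or r not in mirna_index:
            logger.warning("skipping association (%s, %s): unindexed node", g, r)
            continue
        rows.append(gene_index.position(g))
        cols.append(mirna_index.position(r))
    shape = (gene_index.n, mirna_index.n)
    if not rows:
        return sp.csr_matrix(shape)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=shape).tocsr()
    A.data[:] = 1.0
    return A
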