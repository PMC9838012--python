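"""Synthetic heterogeneous-network datasets with planted driver signal.

The generator emulates the statistical shape of the real inputs — three
binary adjacencies over a shared gene universe, per-context omics-derived
attributes, and a partially labelled driver gene set — without any
download.  Drivers are planted through four channels:

* a two-block gene-gene topology (driver-driver edge probability ``p_in``
  vs background ``p_out``),
* elevated attachment to outlying genes and miRNAs
  (``p_po_driver``/``p_po_bg``, ``p_pr_driver``/``p_pr_bg``),
* additive shifts on the per-context mutation / methylation /
  differential-expression rates (Beta-distributed baselines),
* inflated z-score variance for driver-linked outlying genes and shifted
  expression statistics for driver-linked miRNAs.

The two-block topology is the simplest structure that exercises both the
graph convolutions and the link-reconstruction loss; it is not a claim
about real PPI topology.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_model import (GeneIndex, LabeledGeneSet, NetworkBundle, NodeIndex,
                         RunConfig, write_attribute_table, write_config)
from .features import OmicsTables

__all__ = ["SynthConfig", "SyntheticDataset", "generate", "export"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark (defaults = the
    package's standard test-bed instance)."""

    n_genes: int = 300
    n_outlying: int = 150
    n_mirna: int = 60
    n_contexts: int = 4
    samples_per_context: int = 20
    n_diseases: int = 20
    frac_positive: float = 0.15
    p_in: float = 0.10
    p_out: float = 0.02
    driver_mutation_shift: float = 0.5
    driver_expression_shift: float = 0.5
    p_po_driver: float = 0.20
    p_po_bg: float = 0.05
    p_pr_driver: float = 0.15
    p_pr_bg: float = 0.04
    label_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_positive", "p_in", "p_out", "p_po_driver",
                     "p_po_bg", "p_pr_driver", "p_pr_bg", "label_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_genes, self.n_outlying, self.n_mirna, self.n_contexts) < 2:
            raise ValueError("all counts must be >= 2")
        if self.frac_positive * self.n_genes < 2:
            raise ValueError("frac_positive * n_genes must be >= 2")


@dataclass
class SyntheticDataset:
    config: SynthConfig
    gene_ids: list
    outlying_ids: list
    mirna_ids: list
    networks: NetworkBundle
    omics: OmicsTables
    outlying_zscores: dict          # ctx -> m x S
    labels: LabeledGeneSet
    drivers: set
    mutated_mask: np.ndarray = field(default=None)


def _bernoulli(rng, p, shape):
    return (rng.random(shape) < p).astype(np.float64)


def generate(config: SynthConfig = None, seed=None) -> SyntheticDataset:
    """Draw one dataset; bit-identical across calls for a fixed seed."""
    cfg = config if config is not None else SynthConfig()
    if seed is not None:
        cfg = SynthConfig(**{**cfg.__dict__, "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    n, m, t, C = cfg.n_genes, cfg.n_outlying, cfg.n_mirna, cfg.n_contexts
    S = cfg.samples_per_context
    contexts = [f"ctx{k}" for k in range(C)]
    gene_ids = [f"g{k:04d}" for k in range(n)]
    outlying_ids = [f"o{k:04d}" for k in range(m)]
    mirna_ids = [f"mir{k:03d}" for k in range(t)]

    n_drivers = int(round(cfg.frac_positive * n))
    driver_rows = rng.choice(n, size=n_drivers, replace=False)
    is_driver = np.zeros(n, dtype=bool)
    is_driver[driver_rows] = True

    # gene-gene: two-block model on the upper triangle, then symmetrized
    p_mat = np.where(np.outer(is_driver, is_driver), cfg.p_in, cfg.p_out)
    upper = np.triu(rng.random((n, n)) < p_mat, k=1)
    A_PP = sp.csr_matrix((upper | upper.T).astype(np.float64))

    # per-context biological rates: Beta baselines plus driver shifts
    def rates(shift):
        base = rng.beta(2.0, 10.0, size=(n, C))
        return np.clip(base + shift * is_driver[:, None], 0.0, 1.0)

    mut_rate = rates(cfg.driver_mutation_shift)
    meth = rates(cfg.driver_expression_shift)
    de = rates(cfg.driver_expression_shift)
    mutation = {ctx: _bernoulli(rng, mut_rate[:, [k]], (n, S))
                for k, ctx in enumerate(contexts)}
    mutated_mask = np.zeros(n, dtype=bool)
    for ctx in contexts:
        mutated_mask |= mutation[ctx].any(axis=1)

    # bipartite attachments with driver-elevated rates, gated by mutation
    po_p = np.where(is_driver, cfg.p_po_driver, cfg.p_po_bg)[:, None]
    A_PO = _bernoulli(rng, po_p, (n, m)) * mutated_mask[:, None]
    pr_p = np.where(is_driver, cfg.p_pr_driver, cfg.p_pr_bg)[:, None]
    A_PR = _bernoulli(rng, pr_p, (n, t))

    # outlying-gene z-scores: inflated variance when linked to a driver
    driver_linked_o = np.asarray(A_PO[is_driver].sum(axis=0)).ravel() > 0
    sd_o = np.where(driver_linked_o, 1.0 + 2.0 * cfg.driver_expression_shift, 1.0)
    outlying_z = {ctx: rng.normal(0.0, sd_o[:, None], size=(m, S))
                  for ctx in contexts}

    # miRNA statistics: driver-linked miRNAs get shifted means
    driver_linked_r = np.asarray(A_PR[is_driver].sum(axis=0)).ravel() > 0
    mu_r = np.where(driver_linked_r, cfg.driver_expression_shift, 0.0)
    mirna_z = {ctx: rng.normal(mu_r[:, None], 1.0, size=(t, S))
               for ctx in contexts}
    mirna_de = {ctx: rng.normal(mu_r[:, None], 1.0, size=(t, S))
                for ctx in contexts}
    mirna_disease = _bernoulli(rng, 0.15, (t, cfg.n_diseases))

    omics = OmicsTables(
        contexts=contexts,
        mutation=mutation,
        methylation_diff=meth,
        expression_diff=de,
        mirna_zscore=mirna_z,
        mirna_expression_diff=mirna_de,
        mirna_disease=mirna_disease,
    )
    networks = NetworkBundle(A_PP=A_PP, A_PO=sp.csr_matrix(A_PO),
                             A_PR=sp.csr_matrix(A_PR))

    drivers = {gene_ids[k] for k in np.flatnonzero(is_driver)}
    n_labelled = int(round(cfg.label_fraction * n))
    n_neg = max(n_labelled - n_drivers, 1)
    non_driver_rows = np.flatnonzero(~is_driver)
    neg_rows = rng.choice(non_driver_rows, size=min(n_neg, len(non_driver_rows)),
                          replace=False)
    negatives = {gene_ids[k] for k in neg_rows}
    unlabeled = set(gene_ids) - drivers - negatives
    labels = LabeledGeneSet(positives=set(drivers), negatives=negatives,
                            unlabeled=unlabeled)
    return SyntheticDataset(
        config=cfg, gene_ids=gene_ids, outlying_ids=outlying_ids,
        mirna_ids=mirna_ids, networks=networks, omics=omics,
        outlying_zscores=outlying_z, labels=labels, drivers=drivers,
        mutated_mask=mutated_mask)


def _write_edges(path, A, row_ids, col_ids, symmetric=False):
    A = sp.coo_matrix(A)
    with open(path, "w") as fh:
        for i, j in zip(A.row, A.col):
            if symmetric and i >= j:
                continue
            fh.write(f"{row_ids[i]}\t{col_ids[j]}\n")


def export(dataset: SyntheticDataset, out_dir, run_config: RunConfig = None,
           force=False):
    """Write every file the command-line interface consumes: the three edge
    lists, assembled attribute tables (fixed SVD similarity columns for the
    miRNAs, so the tables are self-contained), labels and a run config.
    Refuses a non-empty directory unless ``force``."""
    from dataclasses import replace

    from .pipeline import assemble_attributes

    os.makedirs(out_dir, exist_ok=True)
    if os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")
    cfg = run_config if run_config is not None else RunConfig()
    cfg = replace(cfg, gip_transform="svd")
    attrs = assemble_attributes(dataset, cfg)
    gi = GeneIndex(dataset.gene_ids)
    oi = NodeIndex(dataset.outlying_ids)
    ri = NodeIndex(dataset.mirna_ids)
    net = dataset.networks
    _write_edges(os.path.join(out_dir, "edges_gene_gene.tsv"),
                 net.A_PP, gi.ids, gi.ids, symmetric=True)
    _write_edges(os.path.join(out_dir, "edges_gene_outlying.tsv"),
                 net.A_PO, gi.ids, oi.ids)
    _write_edges(os.path.join(out_dir, "edges_gene_mirna.tsv"),
                 net.A_PR, gi.ids, ri.ids)
    write_attribute_table(os.path.join(out_dir, "gene_attributes.tsv"),
                          gi, attrs.X_P)
    write_attribute_table(os.path.join(out_dir, "outlying_attributes.tsv"),
                          oi, attrs.X_O)
    write_attribute_table(os.path.join(out_dir, "mirna_attributes.tsv"),
                          ri, attrs.X_R)
    with open(os.path.join(out_dir, "labels.tsv"), "w") as fh:
        for g in sorted(dataset.labels.positives):
            fh.write(f"{g}\t1\n")
        for g in sorted(dataset.labels.negatives):
            fh.write(f"{g}\t0\n")
    write_config(os.path.join(out_dir, "config.yaml"), cfg)
    return out_dir
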