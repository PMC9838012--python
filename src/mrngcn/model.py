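"""The MRNGCN model object and its fitted results.

:class:`MRNGCN` bundles the three relationship networks, the node
attributes and the labelled gene partition, and exposes ``fit()`` (full
training on the labelled training genes, statsmodels-style: the returned
:class:`MRNGCNResults` carries per-gene scores, the logistic-regression
combiner weights, loss history, every intermediate feature matrix, and a
``summary()`` table), ``cross_validate()`` and ``ablate()``.

The model is transductive: every gene in the shared index participates in
the graph convolutions, but only labelled *training* genes contribute to
the losses and to the combiner fit, so test-fold scores are leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import training as tr
from ._tensor import Adam, constant, sigmoid, take_rows
from .data_model import AttributeSet, GeneIndex, LabeledGeneSet, NetworkBundle, RunConfig
from .features import AffineLift
from .fusion import Conv1DModule, Conv2DFuse, MlpBranch, combine_synthesis, lr_combine
from .hgcn import (AttentionParams, HgcnParams, bilinear_aggregate,
                   hgcn_stack, hgcn_stack_bipartite, mix_bilinear,
                   pretrain_gene_mirna, self_attention)
from ._tensor import glorot, parameter

BRANCHES = ("gene_gene", "outlying", "mirna")


def _seed_int(*parts):
    """Derive a reproducible 31-bit seed from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


@dataclass
class FeatureBundle:
    """Every intermediate gene representation, as plain arrays."""

    H_branch: dict     # branch name -> n x F (post-HGCN, post-mixing)
    H_att: dict        # branch name -> n x F (post-attention)
    H_1D: dict         # branch name -> n x 1
    H_2D: np.ndarray   # n x 1
    H_mlp: np.ndarray  # n x 1
    H_syn: np.ndarray  # n x 1
    syn_scores: np.ndarray  # n, sigmoid(H_syn)


class MRNGCN:
    """Multi-network heterogeneous graph convolutional driver-gene model."""

    def __init__(self, networks: NetworkBundle, attributes: AttributeSet,
                 labels: LabeledGeneSet, config: RunConfig = None,
                 gene_ids=None):
        self.networks = networks
        self.attributes = attributes
        self.labels = labels
        self.config = config if config is not None else RunConfig()
        if gene_ids is None:
            gene_ids = [f"g{k}" for k in range(networks.n)]
        self.gene_index = gene_ids if isinstance(gene_ids, GeneIndex) else GeneIndex(gene_ids)
        if self.gene_index.n != networks.n:
            raise ValueError("gene id count must match network size")
        known = set(self.gene_index.ids)
        lab = labels.positives | labels.negatives
        if not lab <= known:
            raise ValueError("labelled genes must belong to the gene index")
        self._lab_rows, self._lab_y = labels.labels_for(self.gene_index)
        if len(self._lab_rows) and (self._lab_y == self._lab_y[0]).all():
            raise ValueError("need at least one positive and one negative gene")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dataset(cls, dataset, config=None):
        """Build from a synthetic dataset (see :mod:`mrngcn.synthetic`)."""
        from .pipeline import assemble_attributes

        cfg = config if config is not None else RunConfig()
        attrs = assemble_attributes(dataset, cfg)
        return cls(dataset.networks, attrs, dataset.labels, config=cfg,
                   gene_ids=dataset.gene_ids)

    @classmethod
    def from_files(cls, edges_pp, edges_po, edges_pr, gene_attrs,
                   outlying_attrs, mirna_attrs, labels, config=None):
        """Build from on-disk TSV inputs.  The attribute tables define the
        closed node universes (row order = matrix order); miRNA attribute
        tables must already carry their similarity columns."""
        import pandas as pd

        from .data_model import (NodeIndex, read_attribute_table,
                                 read_edge_list, read_labels)

        def index_of(path, klass=NodeIndex):
            ids = pd.read_csv(path, sep="\t", usecols=[0], dtype=str).iloc[:, 0]
            return klass(ids.tolist())

        gi = index_of(gene_attrs, GeneIndex)
        oi = index_of(outlying_attrs)
        ri = index_of(mirna_attrs)
        bundle = NetworkBundle(
            A_PP=read_edge_list(edges_pp, "symmetric", gi),
            A_PO=read_edge_list(edges_po, "bipartite", gi, oi),
            A_PR=read_edge_list(edges_pr, "bipartite", gi, ri),
        )
        attrs = AttributeSet(
            X_P=read_attribute_table(gene_attrs, gi),
            X_O=read_attribute_table(outlying_attrs, oi),
            X_R=read_attribute_table(mirna_attrs, ri),
        )
        lab = read_labels(labels, gi)
        return cls(bundle, attrs, lab, config=config, gene_ids=gi)

    # -- pre-training ----------------------------------------------------
    def ensure_pretrained(self):
        """Run gene-miRNA pre-training once (unsupervised, shared across
        CV folds); no-op when disabled or already done."""
        cfg = self.config
        if not (cfg.use_mirna and cfg.use_pretrain):
            return
        if self.attributes.X_P_pre is not None:
            return
        Xp, Xr = pretrain_gene_mirna(
            self.networks.A_PR, self.networks.P_PR,
            self.attributes.X_P, self.attributes.X_R,
            epochs=cfg.pretrain_epochs, seed=_seed_int(cfg.seed, 9001),
            hidden_dims=cfg.hidden_dims, lr=cfg.pretrain_lr,
            gip=self.attributes.gip if cfg.gip_transform == "affine" else None,
            sim_dim=cfg.gip_dim, sim_insert=self.attributes.sim_insert,
        )
        self.attributes.X_P_pre = Xp
        self.attributes.X_R_pre = Xr

    # -- parameters ------------------------------------------------------
    def _build_params(self, rng):
        cfg = self.config
        F1 = self.attributes.F1
        P = {"hgcn": HgcnParams(F1, cfg.hidden_dims, rng)}
        if cfg.use_outlying:
            P["lift_O"] = AffineLift(self.attributes.X_O.shape[1], F1, rng=rng)
            if cfg.use_bilinear:
                P["bilinear_W"] = glorot(rng, (F1, cfg.out_dim))
                P["bilinear_b"] = parameter(np.zeros(cfg.out_dim))
        if cfg.use_mirna and not cfg.use_pretrain:
            F3 = self.attributes.X_R.shape[1]
            if self.attributes.gip is not None and cfg.gip_transform == "affine":
                P["gip_lift"] = AffineLift(self.attributes.gip.shape[0],
                                           cfg.gip_dim, rng=rng)
                F3 += cfg.gip_dim
            P["lift_R"] = AffineLift(F3, F1, rng=rng)
        if cfg.use_attention:
            P["attention"] = AttentionParams(
                cfg.out_dim, d=cfg.attention_dim, rng=rng,
                dropout_rate=cfg.dropout_attention)
        for br in self.active_branches:
            P[f"conv1d_{br}"] = Conv1DModule(cfg.out_dim, cfg.conv1d_hidden, rng=rng)
        P["conv2d"] = Conv2DFuse(len(self.active_branches), rng=rng)
        P["mlp"] = MlpBranch(F1, cfg.mlp_hidden, rng=rng)
        return P

    @staticmethod
    def _flat_params(P):
        out = []
        for v in P.values():
            if hasattr(v, "params"):
                out.extend(v.params)
            else:
                out.append(v)
        return out

    @property
    def active_branches(self):
        return self.config.active_branches

    def _X_R_tensor(self, P):
        """Fixed miRNA attributes, or fixed columns with the trainable
        GIP-similarity block inserted."""
        attrs = self.attributes
        if "gip_lift" not in P or attrs.gip is None:
            return constant(attrs.X_R)
        from ._tensor import concat

        k = attrs.sim_insert if attrs.sim_insert is not None else attrs.X_R.shape[1]
        sim = P["gip_lift"](constant(attrs.gip))
        parts = []
        if k > 0:
            parts.append(constant(attrs.X_R[:, :k]))
        parts.append(sim)
        if k < attrs.X_R.shape[1]:
            parts.append(constant(attrs.X_R[:, k:]))
        return concat(parts, axis=1)

    # -- forward ---------------------------------------------------------
    def _forward(self, P, rng=None, training=False):
        cfg = self.config
        net, attrs = self.networks, self.attributes
        X_P = constant(attrs.X_P)
        drop = cfg.dropout_default
        H = {}
        if cfg.use_gene_gene:
            H["gene_gene"] = hgcn_stack(net.P_PP, X_P, P["hgcn"],
                                        dropout_rate=drop, rng=rng,
                                        training=training)
        if cfg.use_outlying:
            X_Ol = P["lift_O"](attrs.X_O)
            G2, _ = hgcn_stack_bipartite(net.P_PO, X_P, X_Ol, P["hgcn"],
                                         dropout_rate=drop, rng=rng,
                                         training=training)
            if cfg.use_bilinear:
                H_BA = bilinear_aggregate(net.A_PO, X_P, X_Ol,
                                          P["bilinear_W"], P["bilinear_b"])
                G2 = mix_bilinear(G2, H_BA, cfg.alpha)
            H["outlying"] = G2
        if cfg.use_mirna:
            if cfg.use_pretrain:
                Xp3 = constant(attrs.X_P_pre)
                Xr3 = constant(attrs.X_R_pre)
            else:
                Xp3 = X_P
                Xr3 = P["lift_R"](self._X_R_tensor(P))
            G3, _ = hgcn_stack_bipartite(net.P_PR, Xp3, Xr3, P["hgcn"],
                                         dropout_rate=drop, rng=rng,
                                         training=training)
            H["mirna"] = G3

        H_att = {}
        for br in self.active_branches:
            if cfg.use_attention:
                H_att[br] = self_attention(H[br], P["attention"], rng=rng,
                                           training=training)
            else:
                H_att[br] = H[br]
        H_1D = {br: P[f"conv1d_{br}"](H_att[br]) for br in self.active_branches}
        H_2D = P["conv2d"]([H_1D[br] for br in self.active_branches])
        H_mlp = P["mlp"](X_P)
        H_syn, syn_scores = combine_synthesis(H_mlp, H_2D)
        return {"H_branch": H, "H_att": H_att, "H_1D": H_1D, "H_2D": H_2D,
                "H_mlp": H_mlp, "H_syn": H_syn, "syn_scores": syn_scores}

    # -- fitting ---------------------------------------------------------
    def fit(self, train_genes=None, seed=None, epochs=None):
        """Train on the given labelled genes (default: all labelled).

        Returns a :class:`MRNGCNResults` with per-gene scores for the
        whole index.  Deterministic for a fixed seed.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        epochs = cfg.epochs if epochs is None else epochs
        self.ensure_pretrained()

        if train_genes is None:
            train_rows, y = self._lab_rows, self._lab_y
        else:
            train_genes = set(train_genes)
            keep = [k for k, r in enumerate(self._lab_rows)
                    if self.gene_index.ids[r] in train_genes]
            train_rows, y = self._lab_rows[keep], self._lab_y[keep]
        if len(train_rows) == 0 or (y == y[0]).all():
            raise ValueError("training set needs both classes")

        rng_init = np.random.default_rng(_seed_int(seed, 1))
        rng_drop = np.random.default_rng(_seed_int(seed, 2))
        rng_neg = np.random.default_rng(_seed_int(seed, 3))
        P = self._build_params(rng_init)
        opt = Adam(self._flat_params(P), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
        use_link = cfg.use_gene_gene
        E = tr.edge_set(self.networks.A_PP) if use_link else None
        history = []
        for epoch in range(epochs):
            out = self._forward(P, rng=rng_drop, training=True)
            l_node = tr.node_bce(take_rows(out["syn_scores"], train_rows), y)
            l_node1 = tr.node_bce(
                take_rows(sigmoid(out["H_2D"]), train_rows), y)
            if use_link and len(E):
                neg = tr.sample_negative_edges(self.networks.A_PP, len(E), rng_neg)
                l_link = tr.link_bce(E, neg, out["H_1D"]["gene_gene"])
            else:
                l_link = None
            loss = tr.total_loss(l_node, l_node1, l_link,
                                 omega1=cfg.omega1, omega2=cfg.omega2)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"node={l_node.data}, node1={l_node1.data}")
            history.append([float(loss.data), float(l_node.data),
                            float(l_node1.data),
                            float(l_link.data) if l_link is not None else 0.0])
            opt.zero_grad()
            loss.backward()
            opt.step()

        out = self._forward(P, training=False)
        bundle = FeatureBundle(
            H_branch={b: h.data.copy() for b, h in out["H_branch"].items()},
            H_att={b: h.data.copy() for b, h in out["H_att"].items()},
            H_1D={b: h.data.copy() for b, h in out["H_1D"].items()},
            H_2D=out["H_2D"].data.copy(),
            H_mlp=out["H_mlp"].data.copy(),
            H_syn=out["H_syn"].data.copy(),
            syn_scores=out["syn_scores"].data.reshape(-1).copy(),
        )
        feature_names = [f"H_1D_{br}" for br in self.active_branches] + ["H_2D", "H_mlp"]
        if cfg.combiner == "lr":
            cols = [bundle.H_1D[br] for br in self.active_branches]
            cols += [bundle.H_2D, bundle.H_mlp]
            scores, w, eps = lr_combine(cols, train_rows, y, C=cfg.lr_C)
        else:
            scores, w, eps = bundle.syn_scores.copy(), None, None
        return MRNGCNResults(
            model=self, params=P, scores_=scores, features_=bundle,
            lr_weights_=w, lr_intercept_=eps, feature_names_=feature_names,
            loss_history_=np.array(history), train_rows_=train_rows,
            train_labels_=y, seed_=seed)

    # -- cross-validation -------------------------------------------------
    def cross_validate(self, folds=None, seed=None, epochs=None):
        """Stratified K-fold CV over the labelled genes; unlabeled genes
        stay in the graphs but never enter losses or the combiner."""
        cfg = self.config
        folds = cfg.cv_folds if folds is None else folds
        seed = cfg.seed if seed is None else seed
        if folds < 2:
            raise ValueError("cv_folds must be >= 2")
        labels = self.labels
        if not labels.fold_of:
            labels = labels.assign_folds(folds, _seed_int(seed, 77))
        ids = self.gene_index.ids
        fold_auc, fold_auprc, oof, weights = [], [], {}, []
        for f in range(folds):
            test_genes = {g for g, ff in labels.fold_of.items() if ff == f}
            train_genes = {g for g in labels.fold_of if g not in test_genes}
            res = self.fit(train_genes=train_genes,
                           seed=_seed_int(seed, 100 + f), epochs=epochs)
            test_rows = np.array([self.gene_index.position(g)
                                  for g in sorted(test_genes)], dtype=np.intp)
            y_test = np.array([1.0 if ids[r] in labels.positives else 0.0
                               for r in test_rows])
            s_test = res.scores_[test_rows]
            auc, auprc = tr.evaluate(s_test, y_test)
            fold_auc.append(auc)
            fold_auprc.append(auprc)
            for g, s in zip(sorted(test_genes), s_test):
                oof[g] = float(s)
            if res.lr_weights_ is not None:
                weights.append(res.lr_weights_)
        return tr.CvResult(fold_auc=fold_auc, fold_auprc=fold_auprc,
                           oof_scores=oof, lr_weights=weights,
                           feature_names=[f"H_1D_{b}" for b in self.active_branches]
                           + ["H_2D", "H_mlp"])

    def ablate(self, variant, folds=None, seed=None, epochs=None):
        """Cross-validate a named ablation variant (see
        ``training.ABLATION_VARIANTS``)."""
        if variant not in tr.ABLATION_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; valid: "
                             f"{sorted(tr.ABLATION_VARIANTS)}")
        cfg = replace(self.config, **tr.ABLATION_VARIANTS[variant])
        clone = MRNGCN(self.networks, self.attributes, self.labels,
                       config=cfg, gene_ids=self.gene_index)
        # pre-training cache is only reusable if the variant still uses it
        if not (cfg.use_mirna and cfg.use_pretrain):
            clone.attributes = replace(self.attributes)  # shallow copy is fine
        return clone.cross_validate(folds=folds, seed=seed, epochs=epochs)


def link_holdout_auc(networks, attributes, labels, config, holdout_frac=0.1,
                     seed=None, epochs=None, gene_ids=None):
    """Hold out a fraction of gene-gene edges, train on the reduced graph,
    and measure how the inner-product decoder on the branch-1 1D features
    ranks the held-out edges against an equal number of sampled non-edges.

    Returns (auc, results).  Note the decoder is rank-1 (one scalar per
    gene), so on graphs whose only pair-level structure is coarse block
    membership its ranking power is intrinsically limited.
    """
    import scipy.sparse as sp

    cfg = config if config is not None else RunConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_seed_int(seed, 55))
    E = tr.edge_set(networks.A_PP)
    k = max(1, int(round(holdout_frac * len(E))))
    held_idx = rng.choice(len(E), size=k, replace=False)
    mask = np.ones(len(E), dtype=bool)
    mask[held_idx] = False
    keep, held = E[mask], E[~mask]
    n = networks.n
    A = sp.coo_matrix((np.ones(len(keep)), (keep[:, 0], keep[:, 1])),
                      shape=(n, n))
    A = ((A + A.T) > 0).astype(np.float64).tocsr()
    reduced = NetworkBundle(A_PP=A, A_PO=networks.A_PO, A_PR=networks.A_PR)
    model = MRNGCN(reduced, attributes, labels, config=cfg, gene_ids=gene_ids)
    res = model.fit(seed=seed, epochs=epochs)
    # negatives sampled against the FULL graph so none is a true edge
    neg = tr.sample_negative_edges(networks.A_PP, len(held), rng)
    s = np.concatenate([res.link_scores(held), res.link_scores(neg)])
    y = np.concatenate([np.ones(len(held)), np.zeros(len(neg))])
    return tr.auc_score(y, s), res


@dataclass
class MRNGCNResults:
    """Fitted model state: per-gene driver scores, combiner weights,
    intermediate features and training diagnostics."""

    model: MRNGCN
    params: dict
    scores_: np.ndarray
    features_: FeatureBundle
    lr_weights_: np.ndarray
    lr_intercept_: float
    feature_names_: list
    loss_history_: np.ndarray     # epochs x [total, node, node1, link]
    train_rows_: np.ndarray
    train_labels_: np.ndarray
    seed_: int

    def evaluate(self, rows=None, labels=None):
        """(AUC, AUPRC) on the given labelled rows (default: the training
        genes — an in-sample diagnostic)."""
        if rows is None:
            rows, labels = self.train_rows_, self.train_labels_
        return tr.evaluate(self.scores_[np.asarray(rows, dtype=np.intp)],
                           labels)

    def link_scores(self, pairs):
        """Reconstructed gene-gene edge probabilities sigmoid(<h_i, h_j>)
        from the branch-1 1D features, for the requested pairs."""
        H = self.features_.H_1D["gene_gene"]
        return tr.link_reconstruction(H, pairs).data

    def top_genes(self, k=30):
        ids = self.model.gene_index.ids
        order = sorted(range(len(ids)), key=lambda i: (-self.scores_[i], ids[i]))
        return [(ids[i], float(self.scores_[i])) for i in order[:k]]

    def write_scores(self, path):
        from .data_model import write_scores

        ids = self.model.gene_index.ids
        lab = []
        for g in ids:
            if g in self.model.labels.positives:
                lab.append("1")
            elif g in self.model.labels.negatives:
                lab.append("0")
            else:
                lab.append("")
        write_scores(path, ids, self.scores_, labels=lab)

    def summary(self):
        cfg = self.model.config
        lines = [
            "MRNGCN driver-gene model",
            "=" * 48,
            f"genes: {self.model.networks.n}   outlying: {self.model.networks.m}"
            f"   miRNAs: {self.model.networks.t}",
            f"branches: {', '.join(self.model.active_branches)}",
            f"layers: {cfg.L} {cfg.hidden_dims}   alpha={cfg.alpha}"
            f"   omega=({cfg.omega1}, {cfg.omega2})",
            f"epochs: {len(self.loss_history_)}   seed: {self.seed_}",
        ]
        if len(self.loss_history_):
            t, n1, n2, lk = self.loss_history_[-1]
            lines.append(f"final loss: total={t:.4f} node={n1:.4f} "
                         f"node_2d={n2:.4f} link={lk:.4f}")
        auc, auprc = self.evaluate()
        lines.append(f"training-set AUC={auc:.4f} AUPRC={auprc:.4f}")
        if self.lr_weights_ is not None:
            lines.append("combiner weights (feature contributions):")
            for name, w in zip(self.feature_names_, self.lr_weights_):
                lines.append(f"  {name:<22s} {w:+.4f}")
            lines.append(f"  {'intercept':<22s} {self.lr_intercept_:+.4f}")
        return "\n".join(lines)
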