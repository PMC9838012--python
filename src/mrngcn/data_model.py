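"""Typed containers and readers/writers for everything the tool touches on disk.

All matrices are indexed by explicit, closed node universes: a
:class:`GeneIndex` (and its outlying-gene / miRNA counterparts) is built from
an id list, never inferred from edge files, so the three relationship
networks share one gene ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "NodeIndex",
    "GeneIndex",
    "NetworkBundle",
    "AttributeSet",
    "LabeledGeneSet",
    "RunConfig",
    "read_id_list",
    "read_edge_list",
    "read_attribute_table",
    "write_attribute_table",
    "read_labels",
    "write_scores",
    "read_scores",
    "read_config",
    "write_config",
]


class NodeIndex:
    """An ordered, closed universe of unique node identifiers.

    The order is the single source of truth for every matrix row/column
    that refers to this node type.
    """

    def __init__(self, ids):
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node ids: {dup[:5]}")
        self.ids = list(ids)
        self._pos = {g: k for k, g in enumerate(self.ids)}

    @property
    def n(self):
        return len(self.ids)

    def __len__(self):
        return len(self.ids)

    def __contains__(self, item):
        return item in self._pos

    def position(self, node_id):
        try:
            return self._pos[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def __eq__(self, other):
        return isinstance(other, NodeIndex) and self.ids == other.ids

    def __repr__(self):
        return f"{type(self).__name__}(n={self.n})"


class GeneIndex(NodeIndex):
    """Gene universe; rows of A_PP, A_PO and A_PR all follow this order."""


def degree_normalize(A):
    """Normalize an adjacency: P[i,j] = A[i,j] / sqrt((rowdeg_i+1)(coldeg_j+1)).

    The +1 shift on both degree sums is applied literally (no self loops are
    inserted); it also makes the division always well defined.  Satisfies
    ``degree_normalize(A.T) == degree_normalize(A).T`` exactly.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    drow = np.asarray(A.sum(axis=1)).ravel() + 1.0
    dcol = np.asarray(A.sum(axis=0)).ravel() + 1.0
    Dr = sp.diags(1.0 / np.sqrt(drow))
    Dc = sp.diags(1.0 / np.sqrt(dcol))
    return (Dr @ A @ Dc).tocsr()


@dataclass
class NetworkBundle:
    """The three binary adjacencies over a shared gene index, plus their
    degree-normalized forms (computed lazily on construction)."""

    A_PP: sp.spmatrix  # genes x genes, symmetric {0,1}
    A_PO: sp.spmatrix  # genes x outlying genes, {0,1}
    A_PR: sp.spmatrix  # genes x miRNAs, {0,1}
    P_PP: sp.spmatrix = None
    P_PO: sp.spmatrix = None
    P_PR: sp.spmatrix = None

    def __post_init__(self):
        self.A_PP = sp.csr_matrix(self.A_PP)
        self.A_PO = sp.csr_matrix(self.A_PO)
        self.A_PR = sp.csr_matrix(self.A_PR)
        n = self.A_PP.shape[0]
        if self.A_PP.shape != (n, n):
            raise ValueError("A_PP must be square")
        if self.A_PO.shape[0] != n or self.A_PR.shape[0] != n:
            raise ValueError("A_PO / A_PR row count must match A_PP")
        if (self.A_PP != self.A_PP.T).nnz:
            raise ValueError("A_PP must be symmetric")
        if self.P_PP is None:
            self.P_PP = degree_normalize(self.A_PP)
        if self.P_PO is None:
            self.P_PO = degree_normalize(self.A_PO)
        if self.P_PR is None:
            self.P_PR = degree_normalize(self.A_PR)

    @property
    def n(self):
        return self.A_PP.shape[0]

    @property
    def m(self):
        return self.A_PO.shape[1]

    @property
    def t(self):
        return self.A_PR.shape[1]

    @property
    def P_OP(self):
        return self.P_PO.T.tocsr()

    @property
    def P_RP(self):
        return self.P_PR.T.tocsr()


@dataclass
class AttributeSet:
    """Initial attribute matrices for the three node types.

    ``X_P`` concatenates per-context biological rates with a topological
    embedding; ``X_O`` and ``X_R`` are lifted to ``X_P``'s width by learnable
    affine maps owned by the model.  ``X_P_pre`` / ``X_R_pre`` are only ever
    produced by pre-training on the gene-miRNA network.
    """

    X_P: np.ndarray              # n x F1
    X_O: np.ndarray              # m x F2
    X_R: np.ndarray              # t x F3
    gip: np.ndarray = None       # t x t GIP kernel (when the similarity block
                                 # is a trainable transform of it)
    X_P_pre: np.ndarray = None   # n x F1, from pre-training
    X_R_pre: np.ndarray = None   # t x F1, from pre-training
    sim_insert: int = None       # column of X_R where a trainable similarity
                                 # block (derived from `gip`) is inserted;
                                 # None when X_R already carries fixed
                                 # similarity columns

    @property
    def F1(self):
        return self.X_P.shape[1]


@dataclass
class LabeledGeneSet:
    """Positive / negative / unlabeled partition of the gene universe with
    stratified fold assignments over the labelled genes."""

    positives: set
    negatives: set
    unlabeled: set
    fold_of: dict = field(default_factory=dict)

    def __post_init__(self):
        p, ng, u = self.positives, self.negatives, self.unlabeled
        if (p & ng) or (p & u) or (ng & u):
            raise ValueError("positives, negatives and unlabeled must be disjoint")
        if self.fold_of:
            labelled = p | ng
            if set(self.fold_of) != labelled:
                raise ValueError("folds must cover exactly the labelled genes")

    def labels_for(self, index: GeneIndex):
        """Return (labelled row positions, 0/1 labels) in index order."""
        rows, y = [], []
        for k, g in enumerate(index.ids):
            if g in self.positives:
                rows.append(k)
                y.append(1.0)
            elif g in self.negatives:
                rows.append(k)
                y.append(0.0)
        return np.array(rows, dtype=np.intp), np.array(y)

    def permuted(self, seed):
        """A label-permuted copy (same labelled genes, positive/negative
        assignment shuffled) — the negative control for planted-signal
        recovery."""
        rng = np.random.default_rng(seed)
        labelled = sorted(self.positives | self.negatives)
        perm = rng.permutation(len(labelled))
        pos = {labelled[i] for i in perm[:len(self.positives)]}
        return LabeledGeneSet(positives=pos, negatives=set(labelled) - pos,
                              unlabeled=set(self.unlabeled))

    def assign_folds(self, k, seed):
        """Stratified fold assignment: positives and negatives are split
        round-robin after a seeded shuffle, so per-fold class ratios stay
        within one gene of the global ratio."""
        rng = np.random.default_rng(seed)
        fold_of = {}
        for group in (sorted(self.positives), sorted(self.negatives)):
            order = list(rng.permutation(len(group)))
            for j, idx in enumerate(order):
                fold_of[group[idx]] = j % k
        for f in range(k):
            members = [g for g, ff in fold_of.items() if ff == f]
            if not any(m in self.positives for m in members):
                raise ValueError(
                    f"fold {f} has no positive gene; use fewer folds")
            if not members:
                raise ValueError(f"fold {f} is empty; use fewer folds")
        return replace(self, fold_of=fold_of)


@dataclass
class RunConfig:
    """Hyperparameters and ablation switches for a full run.

    Defaults follow the published pan-cancer setting: two graph-convolution
    layers of 256 and 128 filters, bilinear mixing weight alpha = 0.2, loss
    weights omega1 = 0.1 and omega2 = 0.01, Adam with learning rate 0.002
    and weight decay 0.0005, dropout 0.5 (0.2 inside self-attention).
    """

    L: int = 2
    hidden_dims: tuple = (256, 128)
    alpha: float = 0.2
    omega1: float = 0.1
    omega2: float = 0.01
    dropout_default: float = 0.5
    dropout_attention: float = 0.2
    learning_rate: float = 0.002
    weight_decay: float = 0.0005
    epochs: int = 1065
    seed: int = 0
    cv_folds: int = 10
    # fusion / combiner details
    conv1d_hidden: int = 32
    mlp_hidden: tuple = (256, 64)
    lr_C: float = 1000.0          # weak L2 on the logistic-regression combiner
    attention_dim: int = None     # defaults to last hidden width
    pretrain_epochs: int = 100
    pretrain_lr: float = 0.01
    gip_dim: int = 16
    gip_transform: str = "affine"  # "affine" (trainable) or "svd" (fixed)
    # ablation switches
    use_gene_gene: bool = True
    use_outlying: bool = True
    use_mirna: bool = True
    use_attention: bool = True
    use_bilinear: bool = True
    use_pretrain: bool = True
    combiner: str = "lr"          # "lr" or "sigmoid_sum"

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("omega1/omega2 must be >= 0")
        for r in (self.dropout_default, self.dropout_attention):
            if not (0.0 <= r < 1.0):
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.combiner not in ("lr", "sigmoid_sum"):
            raise ValueError("combiner must be 'lr' or 'sigmoid_sum'")
        if self.gip_transform not in ("affine", "svd"):
            raise ValueError("gip_transform must be 'affine' or 'svd'")
        self.hidden_dims = tuple(self.hidden_dims)
        self.mlp_hidden = tuple(self.mlp_hidden)
        if len(self.hidden_dims) != self.L:
            raise ValueError("hidden_dims length must equal L")

    @property
    def out_dim(self):
        return self.hidden_dims[-1]

    @property
    def active_branches(self):
        out = []
        if self.use_gene_gene:
            out.append("gene_gene")
        if self.use_outlying:
            out.append("outlying")
        if self.use_mirna:
            out.append("mirna")
        if not out:
            raise ValueError("at least one network must be enabled")
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_id_list(path):
    """One node id per line."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"empty id list: {path}")
    return ids


def read_edge_list(path, kind, row_index, col_index=None):
    """Read a 2-column (optionally 3 with ignored weight) TSV edge list into
    a {0,1} sparse matrix over the given closed indices.

    ``kind='symmetric'`` symmetrizes over a single index and drops self
    loops with a warning; ``kind='bipartite'`` maps column ids against
    ``col_index``.  Duplicate edges collapse to 1; unknown ids are a hard
    error naming the id and line.
    """
    if kind not in ("symmetric", "bipartite"):
        raise ValueError("kind must be 'symmetric' or 'bipartite'")
    if kind == "symmetric":
        col_index = row_index
    if col_index is None:
        raise ValueError("bipartite edge lists need a column index")

    rows, cols = [], []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            a, b = parts[0], parts[1]
            try:
                i = row_index.position(a)
            except KeyError:
                raise ValueError(f"{path}:{lineno}: unknown node id {a!r}") from None
            try:
                j = col_index.position(b)
            except KeyError:
                raise ValueError(f"{path}:{lineno}: unknown node id {b!r}") from None
            if kind == "symmetric" and i == j:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                n_lines += 1
                continue
            rows.append(i)
            cols.append(j)
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"empty edge list: {path}")
    shape = (row_index.n, col_index.n)
    if not rows:
        return sp.csr_matrix(shape)
    data = np.ones(len(rows))
    A = sp.coo_matrix((data, (rows, cols)), shape=shape).tocsr()
    if kind == "symmetric":
        A = A + A.T
    A.data[:] = 1.0  # collapse duplicates
    return A


def read_attribute_table(path, index):
    """Read a TSV attribute table (header row; first column = node id) and
    reorder its rows to match ``index``.  Missing nodes are an error; no
    silent imputation."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    missing = [g for g in index.ids if g not in df.index]
    if missing:
        raise ValueError(f"{path}: missing attribute rows for {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    df = df.loc[index.ids]
    try:
        mat = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}")
        raise
    if np.isnan(mat).any():
        r, c = np.argwhere(np.isnan(mat))[0]
        raise ValueError(f"{path}: non-numeric/missing value at row "
                         f"{index.ids[r]!r}, column {df.columns[c]!r}")
    return mat


def write_attribute_table(path, index, matrix, columns=None):
    matrix = np.asarray(matrix)
    if columns is None:
        columns = [f"f{k}" for k in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=index.ids, columns=columns)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_labels(path, index):
    """Labels TSV: ``gene_id<TAB>{0,1}``; genes absent from the file are
    unlabeled."""
    pos, neg = set(), set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            gid, lab = parts[0], parts[1]
            if gid not in index:
                raise ValueError(f"{path}:{lineno}: unknown gene id {gid!r}")
            if lab == "1":
                pos.add(gid)
            elif lab == "0":
                neg.add(gid)
            else:
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1")
    unlabeled = set(index.ids) - pos - neg
    return LabeledGeneSet(positives=pos, negatives=neg, unlabeled=unlabeled)


def write_scores(path, gene_ids, scores, labels=None):
    """Write per-gene scores sorted by descending score, ties broken by
    gene id (ascending, stable)."""
    scores = np.asarray(scores, dtype=float)
    if len(gene_ids) != len(scores):
        raise ValueError("gene_ids and scores length mismatch")
    if labels is not None and len(labels) != len(gene_ids):
        raise ValueError("labels length mismatch")
    order = sorted(range(len(gene_ids)), key=lambda k: (-scores[k], gene_ids[k]))
    with open(path, "w") as fh:
        for k in order:
            row = [gene_ids[k], f"{scores[k]:.10g}"]
            if labels is not None:
                row.append(str(labels[k]))
            fh.write("\t".join(row) + "\n")


def read_scores(path):
    ids, scores = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or not parts[0]:
                continue
            ids.append(parts[0])
            scores.append(float(parts[1]))
    return ids, np.array(scores)


_TUPLE_FIELDS = {"hidden_dims", "mlp_hidden"}


def read_config(path):
    """Load a RunConfig from a YAML key:value file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def write_config(path, config):
    out = {}
    for f in fields(RunConfig):
        v = getattr(config, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
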