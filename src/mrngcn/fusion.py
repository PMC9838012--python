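"""Feature fusion and the final driver-score combiners.

Each branch's attended gene features are reduced to one scalar per gene by
a 1D-convolution module (two kernel-size-1 convolutions, i.e. per-gene
affine maps with a ReLU between).  The per-branch score columns are then
stacked as channels of an n x 1 image, zero-padded by one, and fused by a
single 3 x 3 2D convolution into H_2D.  An MLP on the original gene
attributes gives H_mlp; H_syn = H_mlp + H_2D drives the node loss, and a
logistic-regression model combines the five per-gene feature columns into
the final driver scores.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import _tensor as T
from ._tensor import Tensor, constant, glorot, matmul, parameter, relu, sigmoid

__all__ = [
    "Conv1DModule",
    "Conv2DFuse",
    "conv2d_fuse",
    "MlpBranch",
    "combine_synthesis",
    "lr_combine",
    "write_lr_report",
]


def _as_t(x):
    return x if isinstance(x, Tensor) else constant(np.asarray(x, dtype=np.float64))


class Conv1DModule:
    """Two successive kernel-size-1 convolutions over an n x F feature
    matrix: per-gene affine maps F -> hidden -> 1 with a ReLU between.
    Kernel size 1 makes the output row depend only on that gene's own
    features."""

    def __init__(self, in_dim, hidden=32, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W1 = glorot(rng, (in_dim, hidden))
        self.b1 = parameter(np.zeros(hidden))
        self.W2 = glorot(rng, (hidden, 1))
        self.b2 = parameter(np.zeros(1))

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def __call__(self, H):
        H = _as_t(H)
        return matmul(relu(matmul(H, self.W1) + self.b1), self.W2) + self.b2


class Conv2DFuse:
    """One 3 x 3 2D convolution fusing B per-branch score columns.

    The B columns are stacked as channels of a (B, n, 1) image and
    zero-padded by one on both spatial dims; with width 1 the only valid
    horizontal kernel position centres on the data column, so the two
    outer kernel columns always see padding zeros.  Output: n x 1.
    """

    def __init__(self, in_channels=3, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan = in_channels * 9
        limit = np.sqrt(6.0 / (fan + 1))
        self.kernel = parameter(rng.uniform(-limit, limit, size=(in_channels, 3, 3)))
        self.bias = parameter(np.zeros(1))
        self.in_channels = in_channels

    @property
    def params(self):
        return [self.kernel, self.bias]

    def __call__(self, columns):
        return conv2d_fuse(columns, self.kernel, self.bias)


def conv2d_fuse(columns, kernel, bias):
    """Apply the padded 3 x 3 convolution to B stacked n x 1 columns.

    Implemented as a dedicated autodiff node: the forward pass only touches
    the kernel's centre column (the outer columns align with padding
    zeros), and their gradients are exactly zero.
    """
    columns = [_as_t(c) for c in columns]
    B = len(columns)
    if kernel.data.shape != (B, 3, 3):
        raise ValueError(f"kernel must be ({B}, 3, 3)")
    n = columns[0].data.shape[0]
    if n < 1:
        raise ValueError("need at least one gene")
    X = np.stack([c.data.reshape(-1) for c in columns], axis=0)  # B x n
    Xpad = np.zeros((B, n + 2))
    Xpad[:, 1:-1] = X

    K = kernel.data
    out = np.full(n, bias.data[0])
    for c in range(B):
        for ky in range(3):
            out += K[c, ky, 1] * Xpad[c, ky:ky + n]
    out = out[:, None]

    def backward(g):
        gflat = g.reshape(-1)
        if kernel.requires_grad or kernel._parents:
            gK = np.zeros_like(K)
            for c in range(B):
                for ky in range(3):
                    gK[c, ky, 1] = gflat @ Xpad[c, ky:ky + n]
            kernel._accumulate(gK)
        if bias.requires_grad or bias._parents:
            bias._accumulate(np.array([gflat.sum()]))
        gpad = np.zeros((B, n + 2))
        for c in range(B):
            for ky in range(3):
                gpad[c, ky:ky + n] += K[c, ky, 1] * gflat
        for c, col in enumerate(columns):
            if col.requires_grad or col._parents:
                col._accumulate(gpad[c, 1:-1].reshape(col.data.shape))

    parents = tuple(columns) + (kernel, bias)
    if any(p.requires_grad or p._parents for p in parents):
        return Tensor(out, parents=parents, backward=backward)
    return Tensor(out)


class MlpBranch:
    """Three-layer perceptron on the original gene attributes:
    Linear3(relu(Linear2(relu(Linear1(X))))), output width 1."""

    def __init__(self, in_dim, hidden=(256, 64), rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        dims = [in_dim, *hidden, 1]
        self.weights, self.biases = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            self.weights.append(glorot(rng, (a, b)))
            self.biases.append(parameter(np.zeros(b)))

    @property
    def params(self):
        return [*self.weights, *self.biases]

    def __call__(self, X):
        H = _as_t(X)
        last = len(self.weights) - 1
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            H = matmul(H, W) + b
            if k < last:
                H = relu(H)
        return H


def combine_synthesis(H_mlp, H_2D):
    """H_syn = H_mlp + H_2D and its sigmoid node scores."""
    H_syn = _as_t(H_mlp) + _as_t(H_2D)
    return H_syn, sigmoid(H_syn)


def lr_combine(feature_columns, train_rows, train_labels, C=1000.0):
    """Fit a logistic-regression combiner on the training-fold genes only
    and score every gene.

    ``feature_columns`` is a list of n x 1 arrays (per-branch 1D features,
    the fused 2D feature, the MLP feature).  Returns (scores, weights,
    intercept); the weights report each feature's contribution.
    """
    F = np.column_stack([np.asarray(c).reshape(-1) for c in feature_columns])
    y = np.asarray(train_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class; cannot fit LR")
    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(F[np.asarray(train_rows, dtype=np.intp)], y)
    scores = clf.predict_proba(F)[:, 1]
    return scores, clf.coef_.ravel().copy(), float(clf.intercept_[0])


def write_lr_report(path, feature_names, weights, intercept):
    with open(path, "w") as fh:
        fh.write("feature\tweight\n")
        for name, w in zip(feature_names, weights):
            fh.write(f"{name}\t{w:.10g}\n")
        fh.write(f"intercept\t{intercept:.10g}\n")
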