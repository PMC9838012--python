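"""Topological node embeddings: biased random walks + skip-gram.

A compact node2vec-style embedder: second-order random walks over the
gene-gene network followed by skip-gram training with negative sampling,
implemented with vectorized numpy minibatch SGD.  With the default return
and in-out parameters p = q = 1 the walks are plain uniform random walks
and fully vectorized; other p/q values fall back to a per-step loop.

Deterministic for a fixed seed.  Isolated nodes receive an all-zero
embedding row.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["random_walks", "skipgram", "node_embedding"]


def random_walks(A, num_walks=10, walk_length=80, p=1.0, q=1.0, seed=0):
    """Generate ``num_walks`` walks of ``walk_length`` steps from every
    non-isolated node.  Returns an int array (walks, walk_length) where
    terminated walks are padded with -1 (only possible via isolated nodes,
    which are excluded as start nodes)."""
    A = sp.csr_matrix(A)
    n = A.shape[0]
    deg = np.diff(A.indptr)
    starts = np.repeat(np.arange(n)[deg > 0], num_walks)
    rng = np.random.default_rng(seed)
    if len(starts) == 0:
        return np.empty((0, walk_length), dtype=np.int64)

    walks = np.full((len(starts), walk_length), -1, dtype=np.int64)
    walks[:, 0] = starts
    if p == 1.0 and q == 1.0:
        cur = starts.copy()
        for step in range(1, walk_length):
            d = deg[cur]
            pick = A.indptr[cur] + (rng.random(len(cur)) * d).astype(np.int64)
            cur = A.indices[pick]
            walks[:, step] = cur
        return walks

    # general second-order walk (per-step loop; small graphs only)
    nbrs = [A.indices[A.indptr[v]:A.indptr[v + 1]] for v in range(n)]
    nbr_sets = [set(x.tolist()) for x in nbrs]
    for w, start in enumerate(starts):
        prev = -1
        cur = start
        for step in range(1, walk_length):
            cand = nbrs[cur]
            if prev < 0:
                nxt = cand[rng.integers(len(cand))]
            else:
                wts = np.where(cand == prev, 1.0 / p,
                               np.where([c in nbr_sets[prev] for c in cand], 1.0, 1.0 / q))
                wts = wts / wts.sum()
                nxt = cand[rng.choice(len(cand), p=wts)]
            walks[w, step] = nxt
            prev, cur = cur, nxt
    return walks


def _walk_pairs(walks, window, rng):
    """Center/context pairs with word2vec-style per-position window
    shrinking (effective window uniform in 1..window)."""
    centers, contexts = [], []
    L = walks.shape[1]
    eff = rng.integers(1, window + 1, size=walks.shape)
    for off in range(1, min(window, L - 1) + 1):
        use = eff[:, :L - off] >= off
        c = walks[:, :L - off][use]
        o = walks[:, off:][use]
        centers.append(c)
        contexts.append(o)
        centers.append(o)
        contexts.append(c)
    return np.concatenate(centers), np.concatenate(contexts)


def skipgram(walks, n_nodes, dim=16, window=10, negatives=5, epochs=2,
             lr=0.5, seed=0):
    """Skip-gram with negative sampling over walk corpora.

    Minibatch SGD (mean gradient per batch, linearly decaying learning
    rate); the negative distribution is the unigram count raised to 3/4.
    Returns the input embedding matrix (n_nodes x dim).
    """
    rng = np.random.default_rng(seed)
    W_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    W_out = np.zeros((n_nodes, dim))
    if walks.size == 0:
        return W_in * 0.0

    counts = np.bincount(walks.ravel()[walks.ravel() >= 0], minlength=n_nodes)
    noise = counts.astype(np.float64) ** 0.75
    noise_sum = noise.sum()
    if noise_sum == 0:
        return W_in * 0.0
    noise /= noise_sum

    centers, contexts = _walk_pairs(walks, window, rng)
    n_pairs = len(centers)
    batch = 1024
    total_steps = epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            idx = order[lo:lo + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(n_nodes, size=(len(idx), negatives), p=noise)
            eta = lr * max(1.0 - step / total_steps, 1e-4)
            step += 1

            vc = W_in[c]                             # B x d
            targets = np.concatenate([o[:, None], neg], axis=1)  # B x (1+k)
            vt = W_out[targets]                      # B x (1+k) x d
            logits = np.clip(np.einsum("bd,bkd->bk", vc, vt), -30.0, 30.0)
            score = 1.0 / (1.0 + np.exp(-logits))
            label = np.zeros_like(score)
            label[:, 0] = 1.0
            err = (score - label) / len(idx)         # mean-gradient batch
            g_c = np.einsum("bk,bkd->bd", err, vt)
            g_t = err[:, :, None] * vc[:, None, :]
            np.add.at(W_in, c, -eta * g_c)
            np.add.at(W_out, targets.ravel(),
                      (-eta * g_t).reshape(-1, W_out.shape[1]))
    return W_in


def node_embedding(A, dim=16, num_walks=10, walk_length=80, window=10,
                   p=1.0, q=1.0, negatives=5, epochs=2, seed=0):
    """Walks + skip-gram; isolated nodes get zero rows."""
    A = sp.csr_matrix(A)
    walks = random_walks(A, num_walks=num_walks, walk_length=walk_length,
                         p=p, q=q, seed=seed)
    emb = skipgram(walks, A.shape[0], dim=dim, window=window,
                   negatives=negatives, epochs=epochs, seed=seed + 1)
    deg = np.diff(A.indptr)
    emb[deg == 0] = 0.0
    return emb
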