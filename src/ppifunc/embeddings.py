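"""node2vec-style node embeddings.

Two stages: (1) second-order biased random walks over the interaction graph
(return parameter ``p`` controls the tendency to backtrack, in-out parameter
``q`` the tendency to venture away from the previous node's neighbourhood);
(2) skip-gram with negative sampling (SGNS) trained on the walk corpus,
implemented as vectorised minibatch SGD in numpy. Single-threaded and fully
deterministic under the seed.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["node2vec_walks", "train_embeddings", "node2vec_embed"]


def node2vec_walks(
    g: nx.Graph,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 10,
    walk_length: int = 80,
    seed: int = 0,
) -> list[list[str]]:
    """Generate second-order biased random walks from every non-isolated node.

    The unnormalised probability of stepping from ``v`` to ``x`` after
    arriving from ``prev`` is ``w(v,x) * a``, with ``a = 1/p`` if ``x`` is
    ``prev`` (return), ``1`` if ``x`` neighbours ``prev`` (stay local) and
    ``1/q`` otherwise (move outward). Walks stop early only at dead ends.
    """
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    rng = np.random.default_rng(seed)
    nbrs: dict = {}
    wts: dict = {}
    for v in g.nodes:
        ns = sorted(g.neighbors(v))
        nbrs[v] = ns
        wts[v] = np.array([g[v][x].get("weight", 1.0) for x in ns], dtype=float)
    nbr_sets = {v: set(ns) for v, ns in nbrs.items()}

    walks: list[list[str]] = []
    for _ in range(walks_per_node):
        for start in sorted(g.nodes):
            if not nbrs[start]:
                continue
            walk = [start]
            w0 = wts[start]
            cur = nbrs[start][rng.choice(len(w0), p=w0 / w0.sum())]
            walk.append(cur)
            while len(walk) < walk_length:
                prev = walk[-2]
                ns = nbrs[cur]
                if not ns:
                    break
                bias = np.empty(len(ns))
                prev_nbrs = nbr_sets[prev]
                for i, x in enumerate(ns):
                    if x == prev:
                        bias[i] = 1.0 / p
                    elif x in prev_nbrs:
                        bias[i] = 1.0
                    else:
                        bias[i] = 1.0 / q
                probs = bias * wts[cur]
                nxt = ns[rng.choice(len(ns), p=probs / probs.sum())]
                walk.append(nxt)
                cur = nxt
            walks.append(walk)
    return walks


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _scatter_mean_update(M: np.ndarray, idx: np.ndarray, grads: np.ndarray,
                         lr: float) -> None:
    """Apply the mean gradient per row. Averaging (not summing) duplicate
    rows keeps the effective step size bounded when the vocabulary is much
    smaller than the batch, which would otherwise diverge."""
    acc = np.zeros_like(M)
    np.add.at(acc, idx, grads)
    cnt = np.bincount(idx, minlength=M.shape[0]).astype(float)[:, None]
    M -= lr * acc / np.maximum(cnt, 1.0)


def train_embeddings(
    walks: Sequence[Sequence[str]],
    d: int = 64,
    window: int = 10,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.1,
    seed: int = 0,
    batch_size: int | None = None,
) -> pd.DataFrame:
    """Train SGNS embeddings on a walk corpus.

    Returns a DataFrame of shape (n_nodes, d) indexed by node, rows being
    the input ("center") vectors. Negative samples are drawn from the
    unigram distribution raised to 3/4; the learning rate decays linearly.
    Duplicate rows within a minibatch contribute the mean of their
    gradients, so the per-row step is bounded by the learning rate; the
    default batch size scales with the corpus so that training always takes
    on the order of 2000 minibatch updates.
    """
    if not walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({tok for w in walks for tok in w})
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)

    # (center, context) pairs for every offset up to the window, symmetric
    centers, contexts = [], []
    for w in walks:
        ids = np.fromiter((index[t] for t in w), dtype=np.int64, count=len(w))
        for off in range(1, min(window, len(ids) - 1) + 1):
            a, b = ids[:-off], ids[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    c_all = np.concatenate(centers)
    o_all = np.concatenate(contexts)

    counts = np.bincount(c_all, minlength=V).astype(float)
    noise = counts**0.75
    noise_cum = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    W = (rng.random((V, d)) - 0.5) / d
    C = np.zeros((V, d))

    n_pairs = len(c_all)
    if batch_size is None:
        # aim for ~2000 minibatches in total so every row accumulates
        # enough movement regardless of corpus size
        batch_size = int(min(4096, max(32, epochs * n_pairs // 2000)))
    total_steps = epochs * n_pairs
    done = 0
    for _ in range(epochs):
        perm = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = perm[lo : lo + batch_size]
            c, o = c_all[sel], o_all[sel]
            lr = alpha * max(1.0 - done / total_steps, 0.01)
            neg = np.searchsorted(
                noise_cum, rng.random((len(sel), negative))
            ).astype(np.int64)
            Uc, Vo, Vn = W[c], C[o], C[neg]
            g_pos = (_sigmoid((Uc * Vo).sum(1)) - 1.0)[:, None]
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", Uc, Vn))
            grad_Uc = g_pos * Vo + np.einsum("bk,bkd->bd", g_neg, Vn)
            _scatter_mean_update(W, c, grad_Uc, lr)
            ctx_idx = np.concatenate([o, neg.ravel()])
            ctx_grad = np.concatenate(
                [g_pos * Uc, (g_neg[..., None] * Uc[:, None, :]).reshape(-1, d)]
            )
            _scatter_mean_update(C, ctx_idx, ctx_grad, lr)
            done += len(sel)
    return pd.DataFrame(W, index=vocab)


def node2vec_embed(
    g: nx.Graph,
    d: int = 64,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 10,
    walk_length: int = 80,
    window: int = 10,
    epochs: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Walks + SGNS in one call, for every node of ``g``.

    Isolated nodes produce no walks and receive the zero vector, so they can
    still be scored downstream (they yield all-zero predictions).
    """
    walks = node2vec_walks(
        g, p=p, q=q, walks_per_node=walks_per_node, walk_length=walk_length,
        seed=seed,
    )
    if walks:
        emb = train_embeddings(walks, d=d, window=window, epochs=epochs, seed=seed)
    else:
        emb = pd.DataFrame(np.zeros((0, d)))
    full = pd.DataFrame(0.0, index=sorted(g.nodes), columns=range(d))
    full.loc[emb.index] = emb.to_numpy()
    return full


def write_embeddings(emb: pd.DataFrame, path) -> None:
    """TSV with a leading ``n d`` dimension line (word2vec text convention)."""
    with open(path, "w") as fh:
        fh.write(f"{emb.shape[0]}\t{emb.shape[1]}\n")
        for node, row in emb.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{node}\t{vals}\n")
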