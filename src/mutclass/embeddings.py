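"""Skip-gram-with-negative-sampling token embeddings.

Both embedding feature families share one trainer: gene "sentences" (a
sample's mutated genes in shuffled order) and random-walk node sequences
are corpora of tokens, and tokens that share contexts end up nearby in
cosine distance.  The objective is the standard skip-gram with negative
sampling: for each (center, context) pair maximize log sigma(u_c . v_o)
plus the expected log sigma(-u_c . v_neg) over noise tokens drawn from
the unigram^0.75 distribution.

Training is plain stochastic gradient descent over the extracted
(center, context) pairs — one update per pair, negatives drawn from a
counter-based generator — with a linearly decaying learning rate.  The
inner loop is JIT-compiled; everything is seeded and single-threaded, so
results are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit


@dataclass
class EmbeddingTable:
    """Trained token vectors plus the hyperparameters that produced them."""

    dim: int
    vectors: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        for tok, v in self.vectors.items():
            if len(v) != self.dim:
                raise ValueError(f"vector for {tok!r} has wrong length")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vectors[a], self.vectors[b]
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        if denom == 0:
            return 0.0
        return float(va @ vb / denom)

    def write_tsv(self, path: str | Path) -> None:
        rows = {tok: v for tok, v in self.vectors.items()}
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"v{i}" for i in range(self.dim)])
        df.to_csv(path, sep="\t", index_label="token")

    @staticmethod
    def read_tsv(path: str | Path) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return EmbeddingTable(
            dim=df.shape[1],
            vectors={str(t): row.to_numpy(dtype=float)
                     for t, row in df.iterrows()},
        )


@njit(cache=False)
def _sgns_epoch(W, C, centers, contexts, order, noise_cdf,
                negative, eta_start, eta_end, state):
    """One SGD epoch of skip-gram negative sampling.

    ``state`` is a 64-bit LCG state used for negative draws; the updated
    state is returned so consecutive epochs continue the stream.
    """
    n = order.shape[0]
    dim = W.shape[1]
    neu1e = np.empty(dim)
    for t in range(n):
        i = order[t]
        c = centers[i]
        o = contexts[i]
        eta = eta_start + (eta_end - eta_start) * (t / n)
        for d in range(dim):
            neu1e[d] = 0.0
        # positive pair: pull center and context together
        dot = 0.0
        for d in range(dim):
            dot += W[c, d] * C[o, d]
        if dot > 30.0:
            s = 1.0
        elif dot < -30.0:
            s = 0.0
        else:
            s = 1.0 / (1.0 + np.exp(-dot))
        g = (1.0 - s) * eta
        for d in range(dim):
            neu1e[d] += g * C[o, d]
            C[o, d] += g * W[c, d]
        # negatives: push noise tokens away
        for _ in range(negative):
            state = state * np.uint64(6364136223846793005) \
                + np.uint64(1442695040888963407)
            u = (state >> np.uint64(11)) * (1.0 / 9007199254740992.0)
            tgt = np.searchsorted(noise_cdf, u)
            if tgt == o:
                continue
            dot = 0.0
            for d in range(dim):
                dot += W[c, d] * C[tgt, d]
            if dot > 30.0:
                s = 1.0
            elif dot < -30.0:
                s = 0.0
            else:
                s = 1.0 / (1.0 + np.exp(-dot))
            g = -s * eta
            for d in range(dim):
                neu1e[d] += g * C[tgt, d]
                C[tgt, d] += g * W[c, d]
        for d in range(dim):
            W[c, d] += neu1e[d]
    return state


def train_skipgram(
    sentences: list[list[str]],
    dim: int,
    window: int,
    epochs: int,
    min_count: int = 1,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.025,
    lr_min: float = 1e-4,
) -> EmbeddingTable:
    """Train token vectors on a corpus of sentences.

    Tokens occurring fewer than ``min_count`` times are dropped from the
    vocabulary (and from sentences) before pair extraction.
    """
    if not sentences:
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = [t for t, c in counts.items() if c >= min_count]
    if not vocab:
        raise ValueError("vocabulary is empty after min_count filtering")
    vocab.sort()
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    centers_list: list[np.ndarray] = []
    contexts_list: list[np.ndarray] = []
    for sent in sentences:
        ids = np.asarray([index[t] for t in sent if t in index], dtype=np.int64)
        L = len(ids)
        if L < 2:
            continue
        for off in range(1, min(window, L - 1) + 1):
            # symmetric pairs at distance `off`
            centers_list.append(ids[:-off])
            contexts_list.append(ids[off:])
            centers_list.append(ids[off:])
            contexts_list.append(ids[:-off])
    rng = np.random.default_rng(seed)
    W = (rng.random((V, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((V, dim))                  # output (context) vectors

    if centers_list:
        centers = np.concatenate(centers_list)
        contexts = np.concatenate(contexts_list)
        n_pairs = len(centers)

        freq = np.asarray([counts[t] for t in vocab], dtype=float) ** 0.75
        noise_cdf = np.cumsum(freq / freq.sum())
        noise_cdf[-1] = 1.0

        state = np.uint64(seed * 2654435761 + 1)
        for ep in range(epochs):
            order = rng.permutation(n_pairs)
            eta_start = max(lr * (1.0 - ep / epochs), lr_min)
            eta_end = max(lr * (1.0 - (ep + 1) / epochs), lr_min)
            state = np.uint64(_sgns_epoch(
                W, C, centers, contexts, order, noise_cdf,
                negative, eta_start, eta_end, state,
            ) & 0xFFFFFFFFFFFFFFFF)

    # expose input + output vectors summed: pairs that predict each other
    # then land nearby even when they share no third-token context
    emb = W + C
    return EmbeddingTable(
        dim=dim,
        vectors={t: emb[i].copy() for t, i in index.items()},
        training_meta={
            "window": window, "epochs": epochs,
            "min_count": min_count, "seed": seed, "negative": negative,
        },
    )


def mean_pool(
    gene_sets: list[frozenset[str] | set[str]],
    table: EmbeddingTable,
    warn_label: str = "sample",
) -> tuple[np.ndarray, list[int]]:
    """Row-wise mean of member-gene vectors; all-absent rows become zero.

    Returns the pooled matrix and the indices of all-absent rows (the
    caller decides how to warn).  Pooling is order-invariant because the
    mean over a set ignores enumeration order.
    """
    out = np.zeros((len(gene_sets), table.dim))
    missing: list[int] = []
    for i, genes in enumerate(gene_sets):
        vecs = [table.vectors[g] for g in sorted(genes) if g in table.vectors]
        if vecs:
            out[i] = np.mean(vecs, axis=0)
        else:
            missing.append(i)
    return out, missing
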