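"""piRNA sequence embedding: 3-mer tokens, skip-gram vectors, TextCNN.

A sequence is split into consecutive overlapping k-mers ("ATTGCAT" ->
ATT, TTG, TGC, GCA, CAT), each k-mer is mapped to a dense vector learned
with a skip-gram model over the whole corpus, and a TextCNN (kernel sizes
1/3/5, global max pooling) condenses the token-vector matrix into one
fixed-length feature per piRNA.

The skip-gram trainer is a compact numpy implementation of negative
sampling: the vocabulary here is at most 4^k tokens, so there is no need
for the machinery of a large-corpus word2vec.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def tokenize_kmers(sequence: str, k: int = 3) -> list:
    """Consecutive overlapping k-mers of ``sequence`` in order (L-k+1 of them)."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} cannot be "
                         f"tokenized into {k}-mers")
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


@dataclass
class KmerVocab:
    """Map from k-mer string to its trained dense vector."""

    k: int
    tokens: list            # vocabulary in fixed order
    vectors: np.ndarray     # len(tokens) x d_w

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.tokens):
            raise ValueError("one vector per token required")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Stack token vectors into an L x d_w matrix."""
        return np.stack([self[t] for t in tokens])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.vectors, index=self.tokens).to_csv(
            path, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path, k: int = 3) -> "KmerVocab":
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls(k=k, tokens=[str(t) for t in df.index],
                   vectors=df.to_numpy(dtype=float))


def train_kmer_embeddings(corpus: Sequence[Sequence[str]], d_w: int = 64,
                          window: int = 5, epochs: int = 5, negative: int = 5,
                          lr: float = 0.025, seed: int = 0) -> KmerVocab:
    """Train skip-gram-with-negative-sampling vectors for every k-mer.

    Each token list is a sentence; for every (center, context) pair within
    ``window`` positions the center vector is pushed toward the context
    vector and away from ``negative`` sampled tokens.  Deterministic for a
    fixed seed (fixed symmetric window, single pass order).
    """
    sentences = [list(s) for s in corpus if len(s) > 0]
    if not sentences:
        raise ValueError("empty corpus")
    counts: dict = {}
    for s in sentences:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    tokens = sorted(counts)
    index = {t: i for i, t in enumerate(tokens)}
    V = len(tokens)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, d_w)) - 0.5) / d_w   # word vectors
    W_out = np.zeros((V, d_w))                  # context vectors
    noise = np.array([counts[t] for t in tokens], dtype=float) ** 0.75
    noise /= noise.sum()

    # precompute (center, context) index pairs per sentence
    pair_lists = []
    for s in sentences:
        idx = np.array([index[t] for t in s])
        centers, contexts = [], []
        for pos in range(len(idx)):
            lo, hi = max(0, pos - window), min(len(idx), pos + window + 1)
            for c in range(lo, hi):
                if c != pos:
                    centers.append(idx[pos])
                    contexts.append(idx[c])
        if centers:
            pair_lists.append((np.array(centers), np.array(contexts)))

    alpha = lr
    n_steps = epochs * len(pair_lists)
    step = 0
    for _ in range(epochs):
        for centers, contexts in pair_lists:
            cur = lr * (1 - step / max(n_steps, 1))
            cur = max(cur, lr * 1e-2)
            P = len(centers)
            neg = rng.choice(V, size=(P, negative), p=noise)
            tgt = np.concatenate([contexts[:, None], neg], axis=1)  # P x (1+neg)
            label = np.zeros((P, 1 + negative))
            label[:, 0] = 1.0
            v = W_in[centers]                       # P x d
            u = W_out[tgt]                          # P x (1+neg) x d
            logits = np.einsum("pd,pkd->pk", v, u)
            g = (label - 1.0 / (1.0 + np.exp(-logits))) * cur  # P x (1+neg)
            dv = np.einsum("pk,pkd->pd", g, u)
            du = g[:, :, None] * v[:, None, :]
            np.add.at(W_in, centers, dv)
            np.add.at(W_out, tgt.ravel(), du.reshape(-1, d_w))
            step += 1

    k = len(tokens[0]) if tokens else 0
    return KmerVocab(k=k, tokens=tokens, vectors=W_in)


# ---------------------------------------------------------------------------
# TextCNN


@dataclass
class TextCNNWeights:
    """Convolution filters and the projection of the pooled feature maps.

    conv_W[s] has shape (s * d_w, n_filters); the s-sized window is
    flattened before the matrix product.  proj_W maps the concatenated
    pooled maps to ``embed_dim``.
    """

    conv_W: dict
    conv_b: dict
    proj_W: np.ndarray
    proj_b: np.ndarray

    @property
    def kernel_sizes(self) -> list:
        return sorted(self.conv_W)

    @property
    def embed_dim(self) -> int:
        return self.proj_W.shape[1]


def init_textcnn_weights(d_w: int, n_filters: int = 128,
                         kernel_sizes: Sequence[int] = (1, 3, 5),
                         embed_dim: int = 128, seed: int = 0) -> TextCNNWeights:
    """Glorot-uniform initialization of all TextCNN parameters."""
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    conv_W = {s: glorot(s * d_w, n_filters) for s in kernel_sizes}
    conv_b = {s: np.zeros(n_filters) for s in kernel_sizes}
    total = n_filters * len(kernel_sizes)
    return TextCNNWeights(conv_W=conv_W, conv_b=conv_b,
                          proj_W=glorot(total, embed_dim),
                          proj_b=np.zeros(embed_dim))


def unfold_windows(X: np.ndarray, size: int) -> np.ndarray:
    """All length-``size`` windows of rows of X, flattened: (L-size+1, size*d)."""
    L, d = X.shape
    return np.stack([X[t:t + size].ravel() for t in range(L - size + 1)])


def pad_tokens(X: np.ndarray, min_len: int) -> np.ndarray:
    """Zero-pad token-vector rows on the right up to ``min_len`` rows."""
    if X.shape[0] >= min_len:
        return X
    pad = np.zeros((min_len - X.shape[0], X.shape[1]))
    return np.vstack([X, pad])


def textcnn_encode(token_vectors: np.ndarray, weights: TextCNNWeights) -> np.ndarray:
    """Encode one sequence's L x d_w token matrix into an embed_dim vector.

    Per kernel size: 1-D convolution over window positions, ReLU, global
    max pool; pooled maps are concatenated and linearly projected.
    """
    sizes = weights.kernel_sizes
    X = pad_tokens(np.asarray(token_vectors, dtype=float), max(sizes))
    pooled = []
    for s in sizes:
        windows = unfold_windows(X, s)                      # T x (s*d_w)
        fmap = np.maximum(windows @ weights.conv_W[s] + weights.conv_b[s], 0.0)
        pooled.append(fmap.max(axis=0))
    feat = np.concatenate(pooled)
    return feat @ weights.proj_W + weights.proj_b


def embed_sequences(records, vocab: KmerVocab,
                    weights: TextCNNWeights) -> np.ndarray:
    """TextCNN features for every piRNA record: m x embed_dim."""
    return np.stack([
        textcnn_encode(vocab.encode(tokenize_kmers(r.sequence, vocab.k)), weights)
        for r in records
    ])
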