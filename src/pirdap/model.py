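"""Heterogeneous GCN with cross-attention encoders and inner-product scoring.

The initial node embedding stacks the TextCNN sequence features of the m
piRNAs (linearly projected to the disease-feature width) on top of the
fused disease similarity rows.  Two symmetrically-normalized graph
convolutions over the heterogeneous adjacency A_h mix the two node types;
two multi-head cross-attention encoders then let piRNAs attend over
disease features and vice versa (residual add + layer norm), and the
association score of pair (i, j) is the inner product of the encoded
feature vectors, mapped to a probability with the logistic function.

Everything is trained end to end with Adam on binary cross-entropy over
the labelled pairs (known positives and PU-selected reliable negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .config import RunConfig
from .nn import Adam, Parameter, Tensor, as_tensor, bce_with_logits, concat, sigmoid
from .seqembed import KmerVocab, pad_tokens, tokenize_kmers, unfold_windows
from .similarity import HeteroGraph


# ---------------------------------------------------------------------------
# spec-level operations (numpy in, numpy out)


def normalize_adjacency(A_h: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A_h D^{-1/2} of the hetero adjacency."""
    A_h = np.asarray(A_h, dtype=float)
    deg = A_h.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero-degree node in heterogeneous adjacency")
    dinv = 1.0 / np.sqrt(deg)
    return A_h * dinv[:, None] * dinv[None, :]


def gcn_layer(A_h: np.ndarray, H: np.ndarray, W: np.ndarray,
              activation: bool = True) -> np.ndarray:
    """One graph convolution: sigma(D^-1/2 A_h D^-1/2 H W)."""
    out = normalize_adjacency(A_h) @ np.asarray(H, float) @ np.asarray(W, float)
    return np.maximum(out, 0.0) if activation else out


def attention_weights(Q: np.ndarray, K: np.ndarray, d_k: int) -> np.ndarray:
    """Row-stochastic attention weight matrix softmax(QK^T / sqrt(d_k))."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    logits = np.asarray(Q, float) @ np.asarray(K, float).T / np.sqrt(d_k)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sda(Q: Tensor, K: Tensor, V: Tensor, d_k: int) -> Tensor:
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    logits = (Q @ K.T) * (1.0 / np.sqrt(d_k))
    return logits.softmax(axis=-1) @ V


def scaled_dot_attention(Q, K, V, d_k: int):
    """softmax(QK^T/sqrt(d_k)) V with row-wise softmax."""
    out = _sda(as_tensor(Q), as_tensor(K), as_tensor(V), d_k)
    return out if isinstance(Q, Tensor) else out.data


@dataclass
class AttentionParams:
    """Per-head projections, output map and post-norm affine of one encoder."""

    W_Q: list            # h matrices d x d_head
    W_K: list
    W_V: list
    W_O: np.ndarray      # (h * d_head) x d
    gamma: np.ndarray    # layer-norm affine scale, length d
    beta: np.ndarray     # layer-norm affine shift, length d

    @property
    def n_heads(self) -> int:
        return len(self.W_Q)

    @property
    def d_k(self) -> int:
        return _dim(self.W_Q[0])[1]


def _dim(w) -> tuple:
    return w.shape if isinstance(w, np.ndarray) else w.data.shape

def _t(w) -> Tensor:
    return w if isinstance(w, Tensor) else Tensor(w)


def init_attention_params(d: int, n_heads: int, rng: np.random.Generator,
                          trainable: bool = True) -> AttentionParams:
    if d % n_heads != 0:
        raise ValueError(f"n_heads ({n_heads}) must divide feature dim ({d})")
    dh = d // n_heads
    make = Parameter if trainable else Tensor

    def mat(fi, fo):
        return make(nn.glorot(rng, fi, fo))

    return AttentionParams(
        W_Q=[mat(d, dh) for _ in range(n_heads)],
        W_K=[mat(d, dh) for _ in range(n_heads)],
        W_V=[mat(d, dh) for _ in range(n_heads)],
        W_O=mat(n_heads * dh, d),
        gamma=make(np.ones(d)),
        beta=make(np.zeros(d)),
    )


def _multi_head(Q: Tensor, K: Tensor, V: Tensor, params: AttentionParams) -> Tensor:
    heads = []
    for wq, wk, wv in zip(params.W_Q, params.W_K, params.W_V):
        dk = _dim(wq)[1]
        heads.append(_sda(Q @ _t(wq), K @ _t(wk), V @ _t(wv), dk))
    return concat(heads, axis=-1) @ _t(params.W_O)


def multi_head(Q, K, V, params: AttentionParams):
    """Concat(head_1..head_h) W_O with head_i = Attention(QW_i^Q, KW_i^K, VW_i^V)."""
    out = _multi_head(as_tensor(Q), as_tensor(K), as_tensor(V), params)
    return out if isinstance(Q, Tensor) else out.data


def _encode_one(H_q: Tensor, H_kv: Tensor, params: AttentionParams) -> Tensor:
    att = _multi_head(H_q, H_kv, H_kv, params)
    normed = (H_q + att).layer_norm()
    return normed * _t(params.gamma) + _t(params.beta)


def encode_pair(H_p, H_d, params_p: AttentionParams, params_d: AttentionParams):
    """Cross-attention encoders: piRNAs attend over diseases and vice versa.

    Each encoder applies multi-head attention (Q from its own side, K and V
    from the other side), a residual add, and layer normalization.
    """
    tp, td = as_tensor(H_p), as_tensor(H_d)
    fp = _encode_one(tp, td, params_p)
    fd = _encode_one(td, tp, params_d)
    if isinstance(H_p, Tensor):
        return fp, fd
    return fp.data, fd.data


def score(F_p, F_d):
    """Inner-product association scores: score[i, j] = <f_i^p, f_j^d>."""
    out = as_tensor(F_p) @ as_tensor(F_d).T
    return out if isinstance(F_p, Tensor) else out.data


# ---------------------------------------------------------------------------
# full model


@dataclass
class ModelInputs:
    """Constant per-fold inputs of the network (no trainable state)."""

    A_h_norm: np.ndarray          # (m+n) x (m+n), symmetric-normalized
    S_d_rows: np.ndarray          # n x n fused disease similarity (H0 disease block)
    token_windows: dict           # kernel size -> (m, T_s, size*d_w) array
    m: int
    n: int
    d_w: int


def prepare_inputs(records, vocab: KmerVocab, hetero: HeteroGraph,
                   S_d_rows: np.ndarray, config: RunConfig) -> ModelInputs:
    """Precompute normalized adjacency and unfolded token windows."""
    max_k = max(config.kernel_sizes)
    mats = [pad_tokens(vocab.encode(tokenize_kmers(r.sequence, vocab.k)), max_k)
            for r in records]
    L = max(x.shape[0] for x in mats)
    stacked = np.stack([pad_tokens(x, L) for x in mats])  # m x L x d_w
    windows = {
        s: np.stack([unfold_windows(x, s) for x in stacked])
        for s in config.kernel_sizes
    }
    return ModelInputs(A_h_norm=normalize_adjacency(hetero.A_h),
                       S_d_rows=np.asarray(S_d_rows, float),
                       token_windows=windows, m=hetero.m, n=hetero.n,
                       d_w=vocab.dim)


class AssociationModel:
    """Trainable TextCNN + hetero-GCN + cross-attention scorer."""

    def __init__(self, inputs: ModelInputs, config: RunConfig, seed: int = 0):
        self.inputs = inputs
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        make = Parameter if c.train_textcnn else Tensor
        self.conv_W = {s: make(nn.glorot(rng, s * inputs.d_w, c.n_filters))
                       for s in c.kernel_sizes}
        self.conv_b = {s: make(np.zeros(c.n_filters)) for s in c.kernel_sizes}
        total = c.n_filters * len(c.kernel_sizes)
        self.proj_W = make(nn.glorot(rng, total, c.embed_dim))
        self.proj_b = make(np.zeros(c.embed_dim))
        # reconcile piRNA feature width with the disease block width
        self.pirna_proj = Parameter(nn.glorot(rng, c.embed_dim, inputs.n))
        dims = [inputs.n] + [c.gcn_dim] * c.gcn_layers
        self.gcn_W = [Parameter(nn.glorot(rng, dims[i], dims[i + 1]))
                      for i in range(c.gcn_layers)]
        self.att_p = init_attention_params(c.gcn_dim, c.n_heads, rng)
        self.att_d = init_attention_params(c.gcn_dim, c.n_heads, rng)

    def parameters(self) -> list:
        ps = [self.pirna_proj, *self.gcn_W]
        if self.config.train_textcnn:
            ps += list(self.conv_W.values()) + list(self.conv_b.values())
            ps += [self.proj_W, self.proj_b]
        for att in (self.att_p, self.att_d):
            ps += att.W_Q + att.W_K + att.W_V + [att.W_O, att.gamma, att.beta]
        return ps

    # -- forward ------------------------------------------------------------

    def sequence_features(self) -> Tensor:
        """TextCNN features of all piRNAs, m x embed_dim."""
        pooled = []
        for s in self.config.kernel_sizes:
            w = Tensor(self.inputs.token_windows[s])       # m x T x (s*d_w)
            fmap = (w @ self.conv_W[s] + self.conv_b[s]).relu()
            pooled.append(fmap.max(axis=1))                # m x F
        return concat(pooled, axis=-1) @ self.proj_W + self.proj_b

    def forward(self) -> Tensor:
        """Logit score matrix, m x n."""
        feats = self.sequence_features()
        H0_p = feats @ self.pirna_proj                     # m x n
        H0 = concat([H0_p, Tensor(self.inputs.S_d_rows)], axis=0)
        Ahat = Tensor(self.inputs.A_h_norm)
        H = H0
        for li, W in enumerate(self.gcn_W):
            H = Ahat @ H @ W
            last = li == len(self.gcn_W) - 1
            if not last or self.config.final_relu:
                H = H.relu()
        H_p, H_d = H[: self.inputs.m], H[self.inputs.m:]
        F_p, F_d = encode_pair(H_p, H_d, self.att_p, self.att_d)
        return score(F_p, F_d)

    def predict(self) -> np.ndarray:
        """Current score matrix as plain numpy (higher = more likely associated)."""
        return self.forward().data


@dataclass
class TrainResult:
    model: AssociationModel
    loss_trace: list
    score_snapshots: list      # score matrices at the last report_window epochs


def train(inputs: ModelInputs, positives: Sequence[tuple],
          reliable_negatives: Sequence[tuple], config: RunConfig,
          seed: int = 0, snapshot_last: int = 0) -> TrainResult:
    """Fit the model with Adam on BCE over the labelled pairs.

    ``positives`` and ``reliable_negatives`` are (piRNA index, disease
    index) pairs and must be disjoint.  Deterministic for a fixed seed.
    """
    positives = [tuple(p) for p in positives]
    negatives = [tuple(p) for p in reliable_negatives]
    if not positives:
        raise ValueError("cannot train without positive pairs")
    if set(positives) & set(negatives):
        raise ValueError("positives and reliable negatives overlap")
    rows = np.array([p[0] for p in positives + negatives])
    cols = np.array([p[1] for p in positives + negatives])
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

    model = AssociationModel(inputs, config, seed=seed)
    opt = Adam(model.parameters(), lr=config.lr)
    trace, snaps = [], []
    for epoch in range(config.epochs):
        opt.zero_grad()
        logits = model.forward()
        loss = bce_with_logits(logits[rows, cols], labels)
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if snapshot_last and epoch >= config.epochs - snapshot_last:
            snaps.append(model.predict())
    return TrainResult(model=model, loss_trace=trace, score_snapshots=snaps)
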