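"""Embedding-token self-attention classifier over four spinal tumor classes.

Each frozen patch embedding (length k) is restructured into t = k/d contiguous
tokens of length d and passed through a small multi-head self-attention stack;
token outputs are mean-pooled and a single softmax layer maps to the class
probabilities P_(meningioma, schwannoma, ependymoma, metastasis).  Training
minimizes cross-entropy against patient-level histopathological labels.  A
linear softmax head with the same interface serves as the ablation baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import CLASSES, N_CLASSES
from .nn import Adam, LayerNorm, Linear, Module, Tensor, cosine_lr, log_softmax

__all__ = [
    "ClassifierConfig",
    "TokenSequence",
    "restructure_embedding",
    "self_attention",
    "TokenTransformerHead",
    "LinearSoftmaxHead",
    "classify_patch",
    "predict_proba",
    "cross_entropy",
    "train_classifier",
    "linear_head_baseline",
    "TrainedClassifier",
]


@dataclass
class TokenSequence:
    """Contiguous, order-preserving segments of one embedding vector."""

    tokens: np.ndarray  # (t, d)
    source_id: str = ""

    def concatenate(self) -> np.ndarray:
        return self.tokens.reshape(-1)


def restructure_embedding(embedding: np.ndarray, token_len: int,
                          source_id: str = "") -> TokenSequence:
    """Split a length-k embedding into k/d contiguous tokens of length d."""
    embedding = np.asarray(embedding)
    k = embedding.shape[-1]
    if token_len <= 0 or k % token_len:
        raise ValueError(f"token length {token_len} does not divide embedding dim {k}")
    return TokenSequence(tokens=embedding.reshape(k // token_len, token_len),
                         source_id=source_id)


def self_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray, d_k: float) -> np.ndarray:
    """Scaled dot-product attention softmax(QK^T / sqrt(d_k)) V (numpy).

    Rows of the attention weight matrix are convex combinations; the output
    rows are therefore convex combinations of the value rows.
    """
    q, k, v = np.asarray(q, float), np.asarray(k, float), np.asarray(v, float)
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValueError(
            f"non-conformable attention shapes Q{q.shape} K{k.shape} V{v.shape}")
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=-1, keepdims=True)
    return weights @ v


@dataclass
class ClassifierConfig:
    token_len: int = 16      # d; must divide the embedding dim
    n_heads: int = 4
    n_layers: int = 2
    ffn_mult: int = 2
    epochs: int = 15
    batch_size: int = 32
    lr: float = 5e-3
    val_fraction: float = 0.10  # grouped by patient, stratified by class
    seed: int = 0
    class_order: tuple = field(default=CLASSES)


class _AttentionBlock(Module):
    """Pre-norm residual block: x + MHA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d: int, n_heads: int, ffn_mult: int, rng):
        if d % n_heads:
            raise ValueError(f"{n_heads} heads incompatible with token dim {d}")
        self.d = d
        self.h = n_heads
        self.dk = d // n_heads
        self.ln1 = LayerNorm(d)
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.ln2 = LayerNorm(d)
        self.ffn1 = Linear(d, ffn_mult * d, rng)
        self.ffn2 = Linear(ffn_mult * d, d, rng)

    def _heads(self, x: Tensor, n: int, t: int) -> Tensor:
        return x.reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        xn = self.ln1(x)
        q = self._heads(self.wq(xn), n, t)
        k = self._heads(self.wk(xn), n, t)
        v = self._heads(self.wv(xn), n, t)
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.dk))
        attn = log_softmax(scores, axis=-1).exp()
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        x = x + self.wo(ctx)
        xn = self.ln2(x)
        return x + self.ffn2(self.ffn1(xn).relu())


class TokenTransformerHead(Module):
    """Self-attention classifier over embedding tokens.

    No positional encodings by default: token positions are fixed segments of
    the embedding, so identity is already implicit; mean-pooling over token
    outputs feeds the single-layer softmax head.
    """

    def __init__(self, embedding_dim: int, config: ClassifierConfig):
        if embedding_dim % config.token_len:
            raise ValueError(
                f"token_len {config.token_len} does not divide "
                f"embedding dim {embedding_dim}")
        rng = np.random.default_rng([config.seed, 7])
        d = config.token_len
        self.embedding_dim = embedding_dim
        self.n_tokens = embedding_dim // d
        self.blocks = [_AttentionBlock(d, config.n_heads, config.ffn_mult, rng)
                       for _ in range(config.n_layers)]
        self.head = Linear(d, N_CLASSES, rng)
        self.config = config

    def logits(self, embeddings: np.ndarray) -> Tensor:
        e = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        n = e.shape[0]
        x = Tensor(e.reshape(n, self.n_tokens, self.config.token_len))
        for blk in self.blocks:
            x = blk(x)
        pooled = x.mean(axis=1)
        return self.head(pooled)


class LinearSoftmaxHead(Module):
    """Ablation baseline: softmax(W x + b) directly on the embedding."""

    def __init__(self, embedding_dim: int, config: ClassifierConfig):
        rng = np.random.default_rng([config.seed, 8])
        self.embedding_dim = embedding_dim
        self.head = Linear(embedding_dim, N_CLASSES, rng)
        self.config = config

    def logits(self, embeddings: np.ndarray) -> Tensor:
        e = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        return self.head(Tensor(e))


def predict_proba(model, embeddings: np.ndarray) -> np.ndarray:
    """Class probability vectors (rows on the simplex) for (n, k) embeddings."""
    emb = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if emb.shape[1] != model.embedding_dim:
        raise ValueError(
            f"embedding length {emb.shape[1]} != model dim {model.embedding_dim}")
    ls = log_softmax(model.logits(emb), axis=-1)
    return np.exp(ls.data)


def classify_patch(embedding: np.ndarray, model) -> np.ndarray:
    """Probability 4-vector for a single embedding (canonical class order)."""
    return predict_proba(model, np.asarray(embedding)[None, :])[0]


def cross_entropy(y_onehot: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    """-sum_c y_c log p_c, with an epsilon floor on probabilities.

    Accepts single vectors or batches (returns the batch mean).
    """
    y = np.atleast_2d(np.asarray(y_onehot, dtype=np.float64))
    probs = np.atleast_2d(np.asarray(p, dtype=np.float64))
    if np.any(probs[y > 0] < eps):
        warnings.warn("probability below epsilon floor in cross-entropy; clipping")
    probs = np.clip(probs, eps, None)
    return float(-(y * np.log(probs)).sum(axis=1).mean())


@dataclass
class TrainedClassifier:
    """A fitted head plus the embedding standardization of its training set."""

    model: object
    history: pd.DataFrame  # epoch, train_loss, val_mean_class_acc
    best_val_acc: float
    emb_mean: np.ndarray | None = None
    emb_scale: np.ndarray | None = None
    class_order: tuple = CLASSES

    def _normalize(self, embeddings: np.ndarray) -> np.ndarray:
        emb = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        if self.emb_mean is None:
            return emb
        return (emb - self.emb_mean) / self.emb_scale

    def predict_proba(self, embeddings: np.ndarray) -> np.ndarray:
        return predict_proba(self.model, self._normalize(embeddings))


def _mean_class_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    vals = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(vals))


def _grouped_split(groups: np.ndarray, y: np.ndarray, frac: float, rng) -> np.ndarray:
    """Hold out ~frac of groups, at least one group per class when possible.

    A class whose patches all come from a single group keeps that group in
    training (it cannot be spared).  If no group can be held out at all, the
    split falls back to a plain ungrouped fraction of patches.
    """
    group_class = {}
    for g, c in zip(groups, y):
        group_class.setdefault(g, c)
    val = set()
    for c in np.unique(y):
        members = np.array(sorted(g for g, gc in group_class.items() if gc == c))
        n_val = min(max(1, int(round(frac * len(members)))), len(members) - 1)
        if n_val > 0:
            val.update(rng.choice(members, size=n_val, replace=False).tolist())
    if val:
        return np.array([g in val for g in groups])
    warnings.warn("every class has a single group; using an ungrouped "
                  "validation split")
    mask = np.zeros(len(groups), dtype=bool)
    k = max(1, int(round(frac * len(groups))))
    mask[rng.choice(len(groups), size=min(k, len(groups) - 1), replace=False)] = True
    return mask


def _train(model, embeddings, labels, groups, config: ClassifierConfig):
    emb = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray([CLASSES.index(l) if isinstance(l, str) else int(l)
                    for l in labels])
    missing = [c for i, c in enumerate(CLASSES) if not np.any(y == i)]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    rng = np.random.default_rng([config.seed, 9])
    groups = (np.asarray(groups) if groups is not None
              else np.arange(len(y)).astype(str))
    val_mask = _grouped_split(groups, y, config.val_fraction, rng)
    if val_mask.all() or (~val_mask).sum() == 0:
        raise ValueError("validation split consumed all training data")
    tr, va = np.flatnonzero(~val_mask), np.flatnonzero(val_mask)
    # standardize embeddings on the training split (stored with the model)
    emb_mean = emb[tr].mean(axis=0)
    emb_scale = emb[tr].std(axis=0) + 1e-8
    emb = (emb - emb_mean) / emb_scale

    params = model.parameters()
    opt = Adam(params, lr=config.lr)
    steps_total = max(1, int(np.ceil(tr.size / config.batch_size))) * config.epochs
    history, best_acc, best_state, step = [], -1.0, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        losses = []
        for b0 in range(0, order.size, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            logits = model.logits(emb[idx])
            ls = log_softmax(logits, axis=-1)
            loss = -ls[np.arange(idx.size), y[idx]].mean()
            for p in params:
                p.grad = None
            loss.backward()
            opt.step(lr=cosine_lr(config.lr, step, steps_total))
            losses.append(float(loss.data))
            step += 1
        val_pred = np.argmax(predict_proba(model, emb[va]), axis=1)
        val_acc = _mean_class_accuracy(y[va], val_pred)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_mean_class_acc": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_arrays()
    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainedClassifier(model=model, history=pd.DataFrame(history),
                             best_val_acc=best_acc, emb_mean=emb_mean,
                             emb_scale=emb_scale)


def train_classifier(embeddings, labels, groups=None,
                     config: ClassifierConfig | None = None) -> TrainedClassifier:
    """Train the token self-attention head on frozen patch embeddings.

    ``labels`` are class names or indices (one per patch, inherited from the
    patient); ``groups`` are patient ids used for the held-out validation
    split.  The returned model is the checkpoint with the best validation
    mean class accuracy.
    """
    config = config or ClassifierConfig()
    emb_dim = np.asarray(embeddings).shape[1]
    model = TokenTransformerHead(emb_dim, config)
    return _train(model, embeddings, labels, groups, config)


def linear_head_baseline(embeddings, labels, groups=None,
                         config: ClassifierConfig | None = None) -> TrainedClassifier:
    """Same training protocol with the linear softmax head (ablation arm)."""
    config = config or ClassifierConfig()
    emb_dim = np.asarray(embeddings).shape[1]
    model = LinearSoftmaxHead(emb_dim, config)
    return _train(model, embeddings, labels, groups, config)
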