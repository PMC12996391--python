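"""Self-supervised patch representation learning (student/teacher, BYOL-style).

The student pathway is encoder f_theta -> projector g_theta -> predictor
q_theta; the teacher pathway is encoder f_xi -> projector g_xi with no
predictor.  For each patch two independently augmented views are drawn; the
loss is the normalized negative cosine similarity

    L = 2 - 2 * <p, z'> / (||p||_2 * ||z'||_2)

between the student prediction p of one view and the teacher projection z' of
the other, symmetrized over the two view orders.  Student parameters update by
gradient descent; teacher parameters only through the exponential moving
average xi <- tau_ema * xi + (1 - tau_ema) * theta and never receive
gradients.  After training only the student encoder is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy, apply_augmentations
from .nn import Adam, MLP, SmallConvEncoder, Tensor, cosine_lr

__all__ = [
    "SSLConfig",
    "SSLNetworks",
    "byol_loss",
    "ema_update",
    "train_ssl",
    "linear_probe_accuracy",
    "save_encoder",
    "load_encoder",
]


@dataclass
class SSLConfig:
    epochs: int = 25
    batch_size: int = 64
    lr: float = 2e-3
    tau_ema: float = 0.996
    embedding_dim: int = 128
    projection_dim: int = 32
    projector_hidden: int = 64
    predictor_hidden: int = 64
    working_size: int = 60  # augment/encode resolution (px); multiple of 30
    val_fraction: float = 0.10  # held out by slide to monitor the loss
    seed: int = 0
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)


class SSLNetworks:
    """Student (encoder, projector, predictor) and teacher (encoder, projector).

    Student and teacher encoders/projectors share identical shapes; the
    teacher starts as a copy of the student and its parameters never require
    gradients.
    """

    def __init__(self, config: SSLConfig):
        c = config
        self.student_encoder = SmallConvEncoder(c.embedding_dim, c.working_size,
                                                seed=c.seed)
        rng = np.random.default_rng([c.seed, 1])
        self.student_projector = MLP(
            [c.embedding_dim, c.projector_hidden, c.projection_dim], rng)
        self.student_predictor = MLP(
            [c.projection_dim, c.predictor_hidden, c.projection_dim], rng)
        self.teacher_encoder = SmallConvEncoder(c.embedding_dim, c.working_size,
                                                seed=c.seed)
        rng_t = np.random.default_rng([c.seed, 1])
        self.teacher_projector = MLP(
            [c.embedding_dim, c.projector_hidden, c.projection_dim], rng_t)
        # teacher = copy of student; frozen (EMA-only updates)
        self.teacher_encoder.load_state_arrays(self.student_encoder.state_arrays())
        self.teacher_projector.load_state_arrays(self.student_projector.state_arrays())
        for p in self.teacher_parameters():
            p.requires_grad = False
        self.config = config

    def student_parameters(self):
        return (self.student_encoder.parameters()
                + self.student_projector.parameters()
                + self.student_predictor.parameters())

    def teacher_parameters(self):
        return self.teacher_encoder.parameters() + self.teacher_projector.parameters()

    def online_parameters(self):
        """Student parameters mirrored by the teacher (encoder + projector)."""
        return self.student_encoder.parameters() + self.student_projector.parameters()

    def student_forward(self, x: Tensor) -> Tensor:
        """Full student pass: y = f(x), z = g(y), p = q(z)."""
        return self.student_predictor(self.student_projector(self.student_encoder(x)))

    def teacher_forward(self, x: np.ndarray | Tensor) -> np.ndarray:
        """Teacher pass stops at the projection; returns plain arrays (no grad)."""
        if isinstance(x, Tensor):
            x = x.data
        z = self.teacher_projector(self.teacher_encoder(Tensor(x)))
        return z.data


def byol_loss(p: np.ndarray, z: np.ndarray) -> float | np.ndarray:
    """Normalized negative cosine similarity, in [0, 4].

    Accepts single vectors or (n, d) batches (returns per-row values).
    """
    p = np.asarray(p, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    z2 = np.atleast_2d(z)
    np_norm = np.linalg.norm(p2, axis=1)
    nz_norm = np.linalg.norm(z2, axis=1)
    if np.any(np_norm == 0) or np.any(nz_norm == 0):
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    cos = (p2 * z2).sum(axis=1) / (np_norm * nz_norm)
    out = 2.0 - 2.0 * cos
    return float(out[0]) if single else out


def _byol_loss_tensor(p: Tensor, z: np.ndarray) -> Tensor:
    """Differentiable batch-mean BYOL loss (z is the detached teacher target)."""
    z = np.asarray(z)
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    p_norm = ((p * p).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    cos = (p / p_norm * zn).sum(axis=1)
    return (2.0 - 2.0 * cos).mean()


def ema_update(student_params, teacher_params, tau_ema: float) -> None:
    """xi <- tau_ema * xi + (1 - tau_ema) * theta, elementwise, in place."""
    if not 0.0 <= tau_ema <= 1.0:
        raise ValueError(f"tau_ema must lie in [0, 1], got {tau_ema}")
    if len(student_params) != len(teacher_params):
        raise ValueError("student/teacher parameter lists differ in length")
    for s, t in zip(student_params, teacher_params):
        if s.data.shape != t.data.shape:
            raise ValueError(f"shape mismatch {s.data.shape} vs {t.data.shape}")
        t.data *= tau_ema
        t.data += (1.0 - tau_ema) * s.data


@dataclass
class SSLTrainResult:
    encoder: SmallConvEncoder
    history: pd.DataFrame  # epoch, loss, lr, val_loss
    config: SSLConfig


def _nchw(views: list[np.ndarray]) -> Tensor:
    return Tensor(np.ascontiguousarray(np.moveaxis(np.stack(views), -1, 1)))


def train_ssl(patches: np.ndarray, config: SSLConfig | None = None,
              slide_ids=None) -> SSLTrainResult:
    """Train the student/teacher scheme on (n, H, W, 3) patches in [0, 1].

    Patches should already be at the working resolution.  A fraction of the
    data (grouped by slide when ``slide_ids`` is given) is held out to monitor
    the loss; it never contributes gradients.  Returns only the student
    encoder plus the loss trajectory.
    """
    config = config or SSLConfig()
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim != 4 or patches.shape[0] == 0:
        raise ValueError("patches must be a non-empty (n, H, W, 3) array")
    nets = SSLNetworks(config)
    if config.epochs <= 0:
        warnings.warn("0 epochs requested; returning the randomly initialized encoder")
        return SSLTrainResult(nets.student_encoder,
                              pd.DataFrame(columns=["epoch", "loss", "lr", "val_loss"]),
                              config)
    rng = np.random.default_rng([config.seed, 2])
    n = patches.shape[0]
    # grouped validation split
    if slide_ids is not None and len(set(slide_ids)) > 1:
        slide_ids = np.asarray(slide_ids)
        uniq = np.array(sorted(set(slide_ids)))
        n_val = max(1, int(round(config.val_fraction * len(uniq))))
        val_slides = set(rng.choice(uniq, size=n_val, replace=False).tolist())
        val_mask = np.array([s in val_slides for s in slide_ids])
    else:
        val_mask = np.zeros(n, dtype=bool)
        k = int(round(config.val_fraction * n))
        if k:
            val_mask[rng.choice(n, size=k, replace=False)] = True
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if train_idx.size == 0:
        raise ValueError("validation split consumed all patches")

    params = nets.student_parameters()
    opt = Adam(params, lr=config.lr)
    steps_per_epoch = max(1, int(np.ceil(train_idx.size / config.batch_size)))
    total_steps = steps_per_epoch * config.epochs
    policy = config.policy
    history, step = [], 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for b0 in range(0, order.size, config.batch_size):
            batch = order[b0:b0 + config.batch_size]
            v1 = [apply_augmentations(patches[i], policy, rng) for i in batch]
            v2 = [apply_augmentations(patches[i], policy, rng) for i in batch]
            x1, x2 = _nchw(v1), _nchw(v2)
            z2 = nets.teacher_forward(x2)
            z1 = nets.teacher_forward(x1)
            p1 = nets.student_forward(x1)
            p2 = nets.student_forward(x2)
            loss = (_byol_loss_tensor(p1, z2) + _byol_loss_tensor(p2, z1)) * 0.5
            for p in params:
                p.grad = None
            loss.backward()
            lr = cosine_lr(config.lr, step, total_steps)
            opt.step(lr=lr)
            ema_update(nets.online_parameters(), nets.teacher_parameters(),
                       config.tau_ema)
            losses.append(float(loss.data))
            step += 1
        val_loss = np.nan
        if val_idx.size:
            vv1 = [apply_augmentations(patches[i], policy, rng) for i in val_idx]
            vv2 = [apply_augmentations(patches[i], policy, rng) for i in val_idx]
            pv = nets.student_forward(_nchw(vv1)).data
            zv = nets.teacher_forward(_nchw(vv2))
            val_loss = float(np.mean(byol_loss(pv, zv)))
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "lr": cosine_lr(config.lr, step, total_steps),
                        "val_loss": val_loss})
    return SSLTrainResult(nets.student_encoder, pd.DataFrame(history), config)


def linear_probe_accuracy(encoder: SmallConvEncoder, patches: np.ndarray,
                          labels: np.ndarray, train_frac: float = 0.5,
                          seed: int = 0) -> float:
    """Mean class accuracy of a least-squares probe on frozen embeddings.

    Fits ridge-regularized least squares from embeddings to one-hot labels on
    a random half of the patches and scores balanced (mean per-class) accuracy
    on the rest.  A diagnostic that the encoder retains class structure.
    """
    labels = np.asarray(labels)
    emb = encoder.embed(np.asarray(patches, dtype=np.float64))
    emb = np.hstack([emb, np.ones((emb.shape[0], 1))])
    classes = sorted(set(labels.tolist()))
    onehot = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    rng = np.random.default_rng(seed)
    n = emb.shape[0]
    order = rng.permutation(n)
    n_tr = int(round(train_frac * n))
    tr, te = order[:n_tr], order[n_tr:]
    a = emb[tr]
    w = np.linalg.solve(a.T @ a + 1e-3 * np.eye(a.shape[1]), a.T @ onehot[tr])
    pred = np.argmax(emb[te] @ w, axis=1)
    true = np.argmax(onehot[te], axis=1)
    per_class = [np.mean(pred[true == k] == k) for k in range(len(classes))
                 if np.any(true == k)]
    return float(np.mean(per_class))


def save_encoder(path, encoder: SmallConvEncoder, config: SSLConfig | None = None):
    arrays = {f"p{i}": a for i, a in enumerate(encoder.state_arrays())}
    meta = dict(embedding_dim=encoder.embedding_dim, in_size=encoder.in_size)
    if config is not None:
        meta.update(seed=config.seed, epochs=config.epochs)
    np.savez(path, _meta=np.array([repr(meta)]), **arrays)


def load_encoder(path) -> SmallConvEncoder:
    import ast

    with np.load(path, allow_pickle=False) as data:
        meta = ast.literal_eval(str(data["_meta"][0]))
        enc = SmallConvEncoder(meta["embedding_dim"], meta["in_size"])
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    enc.load_state_arrays(arrays)
    return enc
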