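"""Network building blocks: linear, convolution, pooling, small encoders.

Convolution is expressed through slicing + matmul primitives of the autodiff
engine (a shifted-window decomposition), which keeps the backward pass exact
and dependency-free.  Kernels here are small (3x3) and inputs are coarse
(<= 64 px), so this is fast enough for CPU-scale training.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "avg_pool2d",
    "LayerNorm",
    "MLP",
    "SmallConvEncoder",
]


class Module:
    """Base class; collects parameters recursively from attributes."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def state_arrays(self):
        """Parameter data arrays, in ``parameters()`` order (for checkpoints)."""
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3x3-style convolution (stride 1) over NCHW tensors."""

    def __init__(self, c_in: int, c_out: int, kernel: int, pad: int,
                 rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k, p = self.kernel, self.pad
        xp = x.pad2d(p)
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        out = None
        for i in range(k):
            for j in range(k):
                win = xp[:, :, i:i + ho, j:j + wo]
                flat = win.transpose(0, 2, 3, 1).reshape(-1, c)
                w_ij = self.weight[:, :, i, j].transpose(1, 0)  # (c_in, c_out)
                contrib = flat @ w_ij
                out = contrib if out is None else out + contrib
        c_out = self.weight.shape[0]
        out = out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
        return out + self.bias.reshape(1, c_out, 1, 1)


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping block-mean pooling of an NCHW tensor."""
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"pool factor {factor} does not divide {h}x{w}")
    return (
        x.reshape(n, c, h // factor, factor, w // factor, factor).mean(axis=(3, 5))
    )


class LayerNorm(Module):
    """Normalization over the last axis with learned scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MLP(Module):
    """Fully connected stack with ReLU between layers (no final activation)."""

    def __init__(self, dims, rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class SmallConvEncoder(Module):
    """Compact convolutional encoder for SRH patches.

    Input: NCHW float tensor at the working resolution (default 60x60, three
    channels in [0,1]).  The image is block-averaged to a 30x30 grid, passed
    through two 3x3 conv/ReLU/pool stages, flattened, and mapped to the
    embedding through a linear layer followed by one residual MLP block.
    Output embeddings have ``embedding_dim`` coordinates.
    """

    def __init__(self, embedding_dim: int = 128, in_size: int = 60,
                 channels=(8, 16), seed: int = 0):
        rng = np.random.default_rng(seed)
        if in_size % 30:
            raise ValueError("in_size must be a multiple of 30")
        self.in_size = in_size
        self.pre_pool = in_size // 30
        c1, c2 = channels
        self.conv1 = Conv2d(3, c1, kernel=3, pad=1, rng=rng)
        self.conv2 = Conv2d(c1, c2, kernel=3, pad=1, rng=rng)
        flat = c2 * 5 * 5
        self.fc = Linear(flat, embedding_dim, rng)
        self.res1 = Linear(embedding_dim, embedding_dim, rng)
        self.res2 = Linear(embedding_dim, embedding_dim, rng)
        self.embedding_dim = embedding_dim

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_size or x.shape[-2] != self.in_size:
            raise ValueError(
                f"encoder expects {self.in_size}x{self.in_size} input, got "
                f"{x.shape[-2]}x{x.shape[-1]}"
            )
        if self.pre_pool > 1:
            x = avg_pool2d(x, self.pre_pool)
        x = avg_pool2d(self.conv1(x).relu(), 2)   # 30 -> 15
        x = avg_pool2d(self.conv2(x).relu(), 3)   # 15 -> 5
        n = x.shape[0]
        x = x.reshape(n, -1)
        e = self.fc(x).relu()
        return e + self.res2(self.res1(e).relu())

    def embed(self, patches: np.ndarray) -> np.ndarray:
        """Embed an (n, H, W, 3) float array; returns (n, embedding_dim)."""
        x = Tensor(np.ascontiguousarray(np.moveaxis(patches, -1, 1)))
        return self.forward(x).data
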