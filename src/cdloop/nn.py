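"""Minimal feed-forward neural-network layers with manual backpropagation.

Only the primitives the loop-calling models need are provided: dense and
convolutional layers, batch normalisation, ReLU/Softplus activations,
average pooling and an Adam optimiser.  Layers follow a uniform contract:
``forward(x, train)`` caches what ``backward(grad)`` needs, ``backward``
accumulates parameter gradients and returns the gradient w.r.t. the input.
All parameters live in ``Param`` objects so an optimiser can iterate them
and checkpoints can round-trip through ``state_dict``.

Arrays are float32 by default; pass ``dtype=np.float64`` at construction
for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "BatchNorm",
    "ReLU",
    "Softplus",
    "Conv2d",
    "AvgPool2d",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "sinusoidal_embedding",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def state_dict(self) -> dict:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]


class Dense(Layer):
    """Affine layer ``x @ W + b`` with He-scaled initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param((rng.standard_normal((n_in, n_out)) * scale).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalisation over axis 0 of an (N, C) array.

    Uses batch statistics in training mode and exponential running
    statistics in evaluation mode, so inference is deterministic.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(dim, dtype=dtype))
        self.beta = Param(np.zeros(dim, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv_std, train, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not train:
            return g * inv_std
        # full batch-norm backward through the batch statistics
        return (inv_std / n) * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))

    def state_dict(self):
        d = super().state_dict()
        d["running_mean"] = self.running_mean
        d["running_var"] = self.running_var
        return d

    def load_state_dict(self, state):
        super().load_state_dict(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Softplus(Layer):
    """log(1 + exp(x)), numerically stable; derivative is the sigmoid."""

    def forward(self, x, train=False):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, grad):
        return grad / (1.0 + np.exp(-self._x))


def _im2col(x: np.ndarray, k: int, pad: int):
    """(N, C, H, W) -> (N, out_h, out_w, C*k*k) patch matrix, stride 1."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = h + 2 * pad - k + 1
    out_w = w + 2 * pad - k + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, (n, c, out_h, out_w, k, k), (s0, s1, s2, s3, s2, s3), writeable=False
    )
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, c * k * k)
    return np.ascontiguousarray(cols), out_h, out_w


class Conv2d(Layer):
    """Stride-1 2-D convolution (cross-correlation) via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad: int = 0, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param((rng.standard_normal((c_out, c_in, k, k)) * scale).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.k, self.pad = k, pad

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.k, self.pad)
        self._cols, self._xshape = cols, x.shape
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)  # (c_out, c_in*k*k)
        out = cols @ wmat.T + self.b.value  # (N, oh, ow, c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        # grad: (N, c_out, oh, ow)
        n, c_out, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1)  # (N, oh, ow, c_out)
        wmat = self.W.value.reshape(c_out, -1)
        self.b.grad += g.sum(axis=(0, 1, 2))
        gflat = g.reshape(-1, c_out)
        self.W.grad += (gflat.T @ self._cols.reshape(-1, self._cols.shape[-1])).reshape(
            self.W.value.shape
        )
        gcols = gflat @ wmat  # (N*oh*ow, c_in*k*k)
        # scatter column gradients back to the (padded) input
        _, c, h, w = self._xshape
        k, pad = self.k, self.pad
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=grad.dtype)
        gcols = gcols.reshape(n, oh, ow, c, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + oh, dj:dj + ow] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        return gx


class AvgPool2d(Layer):
    """Non-overlapping average pooling with square window ``k``."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
        self._xshape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad):
        k = self.k
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        return g


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def state_dict(self):
        return {f"layer{i}.{k}": v for i, l in enumerate(self.layers)
                for k, v in l.state_dict().items()}

    def load_state_dict(self, state):
        for i, l in enumerate(self.layers):
            prefix = f"layer{i}."
            l.load_state_dict({k[len(prefix):]: v for k, v in state.items()
                               if k.startswith(prefix)})


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are integer class indices of shape (N,).
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Transformer-style sinusoidal timestep embedding, shape (N, dim)."""
    t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb
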