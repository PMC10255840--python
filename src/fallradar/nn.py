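"""Minimal CNN building blocks on numpy.

Float32 layers with explicit forward/backward passes, sized for small
spectrogram classifiers: valid (no-padding) 3x3 convolutions via im2col
GEMMs, 2x2 max pooling, ReLU, a fully connected head, softmax
cross-entropy, Adam, and a step-decay learning-rate schedule.

Activations are kept in NHWC layout so that im2col reduces to k*k
contiguous-chunk slice copies and every GEMM reads and writes contiguous
buffers; the input gradient is reconstructed by folding (col2im) rather
than by a second, larger im2col, and the first layer of a network can
skip its input gradient entirely.  On one CPU core this keeps a training
run in the minutes.  All randomness comes from the generator passed at
construction, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B*OH*OW, k*k*C) patches of every valid kxk window.

    Patch element (p, q, c) lands at flat index (p*k + q)*C + c, so the
    innermost C values of each tap are contiguous.
    """
    b, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((b, oh, ow, k, k, c), dtype=x.dtype)
    for p in range(k):
        for q in range(k):
            cols[:, :, :, p, q, :] = x[:, p:p + oh, q:q + ow, :]
    return cols.reshape(b * oh * ow, k * k * c)


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        raise NotImplementedError  # pragma: no cover


class Conv2d(Layer):
    """Valid kxk convolution, stride 1, He-initialized, NHWC."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params = {
            "W": (std * rng.standard_normal((k * k * c_in, c_out))
                  ).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2d expected {self.c_in} channels, got {c}")
        oh, ow = h - self.k + 1, w - self.k + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"Conv2d input {h}x{w} smaller than kernel")
        cols = _im2col(x, self.k)
        self._cache = (cols, (b, h, w))
        y = cols @ self.params["W"]
        y += self.params["b"]
        return y.reshape(b, oh, ow, self.c_out)

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        cols, (b, h, w) = self._cache
        k, c_in = self.k, self.c_in
        oh, ow = dy.shape[1], dy.shape[2]
        dy2 = dy.reshape(-1, self.c_out)
        self.grads["W"] = cols.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        if not need_dx:
            return None
        # fold (col2im): scatter patch gradients back onto the input grid
        dcols = (dy2 @ self.params["W"].T).reshape(b, oh, ow, k, k, c_in)
        dx = np.zeros((b, h, w, c_in), dtype=dcols.dtype)
        for p in range(k):
            for q in range(k):
                dx[:, p:p + oh, q:q + ow, :] += dcols[:, :, :, p, q, :]
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, NHWC (spatial dims must be even).

    The backward pass routes the gradient by value comparison and splits
    it evenly across tied maxima (the exact subgradient); after a ReLU,
    ties essentially only occur at zeros, where the upstream ReLU blocks
    the gradient anyway.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even dims, got {h}x{w}")
        r = x.reshape(b, h // 2, 2, w // 2, 2, c)
        y = np.maximum(np.maximum(r[:, :, 0, :, 0], r[:, :, 0, :, 1]),
                       np.maximum(r[:, :, 1, :, 0], r[:, :, 1, :, 1]))
        self._cache = (r, y)
        return y

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        r, y = self._cache
        b, h2, _, w2, _, c = r.shape
        masks = [(r[:, :, p, :, q, :] == y) for p in range(2)
                 for q in range(2)]
        count = masks[0].astype(y.dtype)
        for m in masks[1:]:
            count += m
        share = dy / count
        g = np.empty_like(r)
        for (p, q), m in zip(((0, 0), (0, 1), (1, 0), (1, 1)), masks):
            np.multiply(m, share, out=g[:, :, p, :, q, :])
        return g.reshape(b, 2 * h2, 2 * w2, c)


class ReLU(Layer):
    """In-place rectifier (consumes its input buffer)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        np.maximum(x, np.float32(0.0), out=x)
        self._out = x
        return x

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        np.multiply(dy, self._out > 0, out=dy)
        return dy


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params = {
            "W": (std * rng.standard_normal((n_in, n_out))
                  ).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T if need_dx else None


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dy: np.ndarray,
                 need_dx: bool = False) -> np.ndarray | None:
        for i, lyr in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            dy = lyr.backward(dy, need_dx=need_dx or not last)
        return dy

    def named_params(self, prefix: str = ""):
        for i, lyr in enumerate(self.layers):
            for name in lyr.params:
                yield f"{prefix}{i}.{name}", lyr


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray,
                  ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient wrt the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam over the (param, grad) slots of a set of layers."""

    def __init__(self, slots: list[tuple[str, Layer]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.slots = slots
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(lyr.params[name.split(".")[-1]])
                  for name, lyr in slots}
        self.v = {name: np.zeros_like(lyr.params[name.split(".")[-1]])
                  for name, lyr in slots}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, lyr in self.slots:
            key = name.split(".")[-1]
            g = lyr.grads[key].astype(lyr.params[key].dtype)
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            lyr.params[key] -= (self.lr * (m / bc1)
                                / (np.sqrt(v / bc2) + self.eps))


def step_lr(base_lr: float, epoch: int, step_size: int,
            gamma: float) -> float:
    """Step-decay schedule: lr = base * gamma^(epoch // step_size)."""
    return base_lr * gamma ** (epoch // step_size)
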