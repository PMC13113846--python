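"""A compact CPU neural-network core: layers, backprop, AdamW.

The trainable classifiers in this package are small convolutional
networks implemented directly on numpy.  Each layer caches what its
backward pass needs; `Sequential` chains layers and can record per-layer
activations and output-gradients, which is what Grad-CAM consumes.
Everything is deterministic given the seed: initialization, batch
shuffling and all numerics are plain single-threaded numpy.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Conv2d",
    "Conv1d",
    "ReLU",
    "AvgPool2d",
    "GlobalAvgPool2d",
    "GlobalAvgPool1d",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "cross_entropy_with_grad",
    "AdamW",
]


def _im2col_indices(C, H, W, k, stride, pad):
    out_h = (H + 2 * pad - k) // stride + 1
    out_w = (W + 2 * pad - k) // stride + 1
    i0 = np.tile(np.repeat(np.arange(k), k), C)
    j0 = np.tile(np.arange(k), k * C)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    ch = np.repeat(np.arange(C), k * k)[:, None]
    return ch, i, j, out_h, out_w


class Layer:
    params: list  # list of [array, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=False, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float64
        )
        self.dW = np.zeros_like(self.W)
        self.params = [[self.W, self.dW]]
        self.b = np.zeros(out_ch) if bias else None
        if bias:
            self.db = np.zeros(out_ch)
            self.params.append([self.b, self.db])
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.padding = stride, padding
        self._cache = None

    def forward(self, x):
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise InvalidInputError(f"expected {self.in_ch} channels, got {C}")
        ch, i, j, out_h, out_w = _im2col_indices(
            C, H, W, self.kernel, self.stride, self.padding
        )
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2))
        cols = xp[:, ch, i, j]  # (B, C*k*k, L)
        out = np.matmul(self.W[None], cols)  # (B, O, L)
        if self.b is not None:
            out = out + self.b[None, :, None]
        self._cache = (cols, (ch, i, j), xp.shape, (H, W))
        return out.reshape(B, self.out_ch, out_h, out_w)

    def backward(self, grad):
        cols, (ch, i, j), xp_shape, (H, W) = self._cache
        B = grad.shape[0]
        g = grad.reshape(B, self.out_ch, -1)  # (B, O, L)
        self.dW += np.einsum("bol,bcl->oc", g, cols)
        if self.b is not None:
            self.db += g.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], g)  # (B, C*k*k, L)
        dxp = np.zeros(xp_shape)
        np.add.at(dxp, (np.arange(B)[:, None, None], ch, i, j), dcols)
        p = self.padding
        return dxp[:, :, p : p + H, p : p + W] if p else dxp

    def macs(self, in_side: int) -> int:
        out_side = (in_side + 2 * self.padding - self.kernel) // self.stride + 1
        return self.kernel**2 * self.in_ch * self.out_ch * out_side**2

    def out_side(self, in_side: int) -> int:
        return (in_side + 2 * self.padding - self.kernel) // self.stride + 1


class Conv1d(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=False, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel
        self.W = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float64
        )
        self.dW = np.zeros_like(self.W)
        self.params = [[self.W, self.dW]]
        self.b = np.zeros(out_ch) if bias else None
        if bias:
            self.db = np.zeros(out_ch)
            self.params.append([self.b, self.db])
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.padding = stride, padding

    def forward(self, x):
        B, C, L = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        out_l = (L + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        i = (s * np.arange(out_l)[None, :] + np.arange(k)[:, None]).ravel()
        ch = np.repeat(np.arange(C), k)[:, None]
        pos = np.tile(i.reshape(k, out_l), (C, 1))
        cols = xp[:, ch, pos]  # (B, C*k, out_l)
        out = np.matmul(self.W[None], cols)
        if self.b is not None:
            out = out + self.b[None, :, None]
        self._cache = (cols, ch, pos, xp.shape, L)
        return out

    def backward(self, grad):
        cols, ch, pos, xp_shape, L = self._cache
        B = grad.shape[0]
        self.dW += np.einsum("bol,bcl->oc", grad, cols)
        if self.b is not None:
            self.db += grad.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], grad)
        dxp = np.zeros(xp_shape)
        np.add.at(dxp, (np.arange(B)[:, None, None], ch, pos), dcols)
        p = self.padding
        return dxp[:, :, p : p + L] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2d(Layer):
    """Non-overlapping average pooling by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        B, C, H, W = x.shape
        f = self.factor
        if H % f or W % f:
            raise InvalidInputError(f"spatial size {H}x{W} not divisible by {f}")
        self._in_shape = x.shape
        return x.reshape(B, C, H // f, f, W // f, f).mean(axis=(3, 5))

    def backward(self, grad):
        f = self.factor
        g = grad[:, :, :, None, :, None] / (f * f)
        g = np.broadcast_to(g, grad.shape[:2] + (grad.shape[2], f, grad.shape[3], f))
        return g.reshape(self._in_shape)


class GlobalAvgPool2d(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._in_shape
        return np.broadcast_to(grad[:, :, None, None] / (H * W), self._in_shape).copy()


class GlobalAvgPool1d(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=2)

    def backward(self, grad):
        B, C, L = self._in_shape
        return np.broadcast_to(grad[:, :, None] / L, self._in_shape).copy()


class Flatten(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, n_in, n_out, bias=True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float64)
        self.dW = np.zeros_like(self.W)
        self.params = [[self.W, self.dW]]
        self.b = np.zeros(n_out) if bias else None
        if bias:
            self.db = np.zeros(n_out)
            self.params.append([self.b, self.db])
        self.n_in, self.n_out = n_in, n_out

    def forward(self, x):
        self._x = x
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def backward(self, grad):
        self.dW += self._x.T @ grad
        if self.b is not None:
            self.db += grad.sum(axis=0)
        return grad @ self.W.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, record: bool = False):
        acts = [] if record else None
        for layer in self.layers:
            x = layer.forward(x)
            if record:
                acts.append(x)
        self._acts = acts
        return x

    def backward(self, grad, record: bool = False):
        grads = [None] * len(self.layers) if record else None
        for idx in range(len(self.layers) - 1, -1, -1):
            if record:
                grads[idx] = grad  # gradient w.r.t. this layer's output
            grad = self.layers[idx].backward(grad)
        self._out_grads = grads
        return grad

    def parameters(self):
        return [pair[0] for layer in self.layers for pair in layer.params]

    def param_pairs(self):
        return [pair for layer in self.layers for pair in layer.params]

    def zero_grad(self):
        for _, g in self.param_pairs():
            g[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.param_pairs()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), saved in zip(self.param_pairs(), state):
            p[...] = saved


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(self, param_pairs, lr=1e-3, weight_decay=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.pairs = param_pairs
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in param_pairs]
        self.v = [np.zeros_like(p) for p, _ in param_pairs]

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
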