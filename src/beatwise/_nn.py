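"""A compact numpy implementation of the 1-D CNN building blocks.

Layers keep float32 buffers and implement forward/backward explicitly
(im2col convolutions, argmax-cached max pooling, inverted dropout) with an
Adam optimiser.  Sized for detector-scale problems: tens of thousands of
512-sample inputs on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv1D:
    """Same-padded stride-1 1-D convolution, He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0, scale, (c_in * kernel, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (B, C, L) -> (B, c_out, L)
        B, C, L = x.shape
        k = self.kernel
        pad_l = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, k - 1 - pad_l)))
        cols = sliding_window_view(xp, k, axis=2)          # (B, C, L, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(B * L, C * k)
        out = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._shape = (B, C, L)
        return out.reshape(B, L, self.c_out).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        k = self.kernel
        g = grad.transpose(0, 2, 1).reshape(B * L, self.c_out)
        self.dW = self._cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(B, L, C, k).transpose(0, 2, 1, 3)
        pad_l = (k - 1) // 2
        dxp = np.zeros((B, C, L + k - 1), dtype=np.float32)
        for p in range(k):
            dxp[:, :, p:p + L] += dcols[:, :, :, p]
        del self._cols
        return dxp[:, :, pad_l:pad_l + L]

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class MaxPool1D:
    """Non-overlapping pooling; odd tails are edge-padded first."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train):
        B, C, L = x.shape
        s = self.size
        if L % s:
            x = np.pad(x, ((0, 0), (0, 0), (0, s - L % s)), mode="edge")
        Lp = x.shape[2]
        xr = x.reshape(B, C, Lp // s, s)
        if train:
            self._arg = xr.argmax(axis=3)
            self._in_len = L
        return xr.max(axis=3)

    def backward(self, grad):
        B, C, Lo = grad.shape
        s = self.size
        dx = np.zeros((B, C, Lo, s), dtype=np.float32)
        np.put_along_axis(dx, self._arg[..., None], grad[..., None], axis=3)
        dx = dx.reshape(B, C, Lo * s)
        return dx[:, :, : self._in_len]

    def params(self):
        return []


class Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def params(self):
        return []


class Dropout:
    """Inverted dropout: identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(np.float32)

    def backward(self, grad):
        if self.p <= 0:
            return grad
        return grad * self._mask

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, y: np.ndarray):
    """Mean CE loss and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self):
        self.t += 1
        for layer in self.layers:
            for param, grad_name in layer.params():
                grad = getattr(layer, grad_name)
                key = id(param)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self.state[key]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name in ("W", "b"):
                if hasattr(layer, name):
                    out[f"{li}.{name}"] = getattr(layer, name)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            li, name = key.split(".")
            getattr(self.layers[int(li)], name)[...] = value
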