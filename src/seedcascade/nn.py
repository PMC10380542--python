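"""Minimal 1-D convolutional network stack on numpy.

Implements exactly the pieces the multireceptive-field spectral classifier
needs: same-padded stride-1 Conv1d, MaxPool1d (kernel 3 / stride 2 /
padding 1), ReLU, a fully connected head, Kaiming-normal initialization,
softmax cross-entropy and Adam.  Forward passes cache what the analytic
backward pass needs; gradients flow to parameters *and* to the input, which
is what the guided input-optimization in :mod:`seedcascade.selection`
relies on.

All layers are deterministic given the init rng; matmuls are the only
vectorized primitives used, so results are bit-reproducible on one thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """He-style fan-in normal init: std = sqrt(2 / fan_in)."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d:
    """Stride-1 cross-correlation with 'same' zero padding.

    Weights are ``(c_out, c_in, k)``; inputs/outputs ``(B, C, L)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel % 2 == 0:
            raise ValueError("same-padding conv needs an odd kernel")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = (kernel - 1) // 2
        self.W = kaiming_normal(rng, (c_out, c_in, kernel), c_in * kernel, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        self._in_shape = x.shape
        if self.pad:
            xp = np.zeros((B, C, L + 2 * self.pad), dtype=x.dtype)
            xp[:, :, self.pad:self.pad + L] = x
        else:
            xp = x
        # (B, C, L, k) windows -> (B*L, C*k) design matrix
        win = sliding_window_view(xp, self.kernel, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, C * self.kernel)
        self._cols = cols
        out = cols @ self.W.reshape(self.c_out, -1).T + self.b
        return out.reshape(B, L, self.c_out).transpose(0, 2, 1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 1)).reshape(B * L, self.c_out)
        self.dW[...] = (g2.T @ self._cols).reshape(self.W.shape)
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.reshape(self.c_out, -1)).reshape(B, L, C, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, L, k)
        dxp = np.zeros((B, C, L + 2 * self.pad), dtype=gy.dtype)
        for i in range(self.kernel):
            dxp[:, :, i:i + L] += dcols[:, :, :, i]
        return dxp[:, :, self.pad:self.pad + L] if self.pad else dxp


class MaxPool1d:
    """Max pooling, default kernel 3 / stride 2 / padding 1.

    Output length is ``floor((L + 2*pad - kernel) / stride) + 1``.
    """

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @staticmethod
    def out_length(L: int, kernel: int = 3, stride: int = 2, pad: int = 1) -> int:
        return (L + 2 * pad - kernel) // stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        self._in_shape = x.shape
        xp = np.full((B, C, L + 2 * self.pad), -np.inf, dtype=x.dtype)
        xp[:, :, self.pad:self.pad + L] = x
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        self._argmax = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        L_out = gy.shape[2]
        dxp = np.zeros((B, C, L + 2 * self.pad), dtype=gy.dtype)
        starts = self.stride * np.arange(L_out)
        for j in range(self.kernel):
            mask = self._argmax == j
            dxp[:, :, starts + j] += gy * mask  # starts+j has no duplicates for fixed j
        return dxp[:, :, self.pad:self.pad + L]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = kaiming_normal(rng, (n_out, n_in), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.dW[...] = gy.T @ self._x
        self.db[...] = gy.sum(axis=0)
        return gy @ self.W


def softmax(z: np.ndarray) -> np.ndarray:
    """Max-shifted softmax along the last axis."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(B), targets], 1e-30, None)).mean())
    grad = p.astype(logits.dtype)
    grad[np.arange(B), targets] -= 1.0
    return loss, grad / B


class Adam:
    """Adaptive-moment SGD (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)  # list of (value, grad) array pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
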