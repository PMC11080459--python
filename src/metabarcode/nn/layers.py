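"""Neural-network layers with analytic forward/backward passes.

Layers operate internally in channels-last layout (batch, length, channels):
the im2col gather ``x[:, idx]`` then lands directly in the (B*L_out, K*C)
matrix a BLAS matmul wants, with no transpose copies.  The model wrapper
converts from the external (batch, channels, length) convention once per
pass.  Convolutions are "valid" (no padding):
L_out = floor((L_in - kernel) / stride) + 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ReLU", "Dropout", "Flatten", "Linear", "conv_out_len"]

DTYPE = np.float32


def conv_out_len(l_in: int, kernel: int, stride: int) -> int:
    return (l_in - kernel) // stride + 1


class Layer:
    """Base: stateless unless it carries weights."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """1D convolution on (B, L, C) activations; weights (K*C_in, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        fan_in = c_in * kernel
        # He initialization (ReLU nonlinearities follow the convolutions)
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (kernel * c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._idx: np.ndarray | None = None
        self._l_in = -1

    def _indices(self, l_in: int) -> np.ndarray:
        if l_in != self._l_in:
            l_out = conv_out_len(l_in, self.kernel, self.stride)
            if l_out < 1:
                raise ValueError(f"input length {l_in} shorter than kernel "
                                 f"{self.kernel}")
            self._idx = (np.arange(l_out)[:, None] * self.stride
                         + np.arange(self.kernel)[None, :])
            self._l_in = l_in
        return self._idx

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l_in, _ = x.shape
        idx = self._indices(l_in)
        l_out = idx.shape[0]
        if self.kernel == 1 and self.stride == 1:
            cols = x.reshape(b * l_in, self.c_in)
        else:
            # (B, L_out, K, C) is already contiguous in matmul order
            cols = x[:, idx, :].reshape(b * l_out, self.kernel * self.c_in)
        self._cols, self._in_shape = cols, x.shape
        y = cols @ self.W
        y += self.b
        return y.reshape(b, l_out, self.c_out)

    def backward(self, dy: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
        b, l_out, _ = dy.shape
        dyf = dy.reshape(b * l_out, self.c_out)
        self.dW[...] = self._cols.T @ dyf
        self.db[...] = dyf.sum(axis=0)
        if not need_input_grad:
            return None
        if self.kernel == 1 and self.stride == 1:
            return (dyf @ self.W.T).reshape(self._in_shape)
        dcols = (dyf @ self.W.T).reshape(b, l_out, self.kernel, self.c_in)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        if self.stride == 1:
            for t in range(self.kernel):
                dx[:, t:t + l_out, :] += dcols[:, :, t, :]
        else:
            starts = self._indices(self._in_shape[1])[:, 0]
            # per kernel offset the target positions are distinct, so fancy
            # indexing accumulates without collisions
            for t in range(self.kernel):
                dx[:, starts + t, :] += dcols[:, :, t, :]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape, dtype=DTYPE) >= self.p) \
            .astype(DTYPE) / DTYPE(1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in),
                            (n_out, n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]
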