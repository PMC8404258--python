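"""Minimal 1-D neural-network layers with exact analytic gradients.

Implements exactly the layer set the classifier needs - valid-padding 1-D
convolution with ReLU, non-overlapping max pooling, a GRU that returns its
final hidden state (classic reset-before-matmul gating), output dropout
and a dense softmax head - together with an L2-regularised cross-entropy
loss and an Adam optimizer.  Shapes follow the (batch, time, channels)
convention throughout.  Gradients are hand-derived and checked against
central finite differences in the test suite.

The networks trained here are small (a few thousand parameters, sequence
length 9 after pooling), so plain BLAS-backed numpy is entirely adequate
on one CPU core.
"""

from __future__ import annotations

import math
import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int, dtype) -> np.ndarray:
    n = max(rows, cols)
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return np.ascontiguousarray(q[:rows, :cols], dtype=dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    """Base class: trainable arrays live in ``params``; gradients of the
    last backward pass in ``grads`` under the same keys.  Keys starting
    with ``W`` or ``U`` are weights (L2-decayed); ``b*`` are biases."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding stride-1 1-D convolution, optional ReLU.

    Input (B, T, C_in) -> output (B, T - kernel + 1, filters).
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 relu: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        self.relu = relu
        fan_in = kernel * in_channels
        self.params["W"] = _glorot(rng, (fan_in, filters), fan_in, filters, dtype)
        self.params["b"] = np.zeros(filters, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        t_out = T - self.kernel + 1
        if t_out < 1:
            raise ValueError(f"input length {T} shorter than kernel {self.kernel}")
        # (B, T_out, C, K) -> (B, T_out, K*C) columns
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, t_out, -1)
        z = cols @ self.params["W"] + self.params["b"]
        self._cols = cols
        self._x_shape = x.shape
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        B, t_out, F = dy.shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dy2 = dy.reshape(-1, F)
        self.grads["W"] = cols2.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(B, t_out, self.kernel, self.in_channels)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        for k in range(self.kernel):
            dx[:, k:k + t_out, :] += dcols[:, :, k, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = pool size), valid truncation:
    output length floor((T - pool) / pool) + 1."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        t_out = (T - self.pool) // self.pool + 1
        if t_out < 1:
            raise ValueError(f"input length {T} shorter than pool {self.pool}")
        xr = x[:, :t_out * self.pool].reshape(B, t_out, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._x_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, t_out, C = dy.shape
        dxr = np.zeros((B, t_out, self.pool, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        dx[:, :t_out * self.pool] = dxr.reshape(B, t_out * self.pool, C)
        return dx


class GRU(Layer):
    """Gated recurrent unit returning the final hidden state.

    Classic formulation: z and r gates are sigmoids of input and previous
    state; the candidate uses the reset gate on the previous state before
    its recurrent matmul (``tanh(x Wc + (r * h) Uc + bc)``); the new state
    is ``(1 - z) * h + z * candidate``.  Dropout (inverted scaling) is
    applied to the returned state during training only.
    """

    def __init__(self, in_dim: int, units: int, dropout: float = 0.0,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.in_dim = in_dim
        self.dropout = dropout
        self._rng = rng
        H = units
        self.params["W"] = _glorot(rng, (in_dim, 3 * H), in_dim, H, dtype)  # x -> [z, r, c]
        self.params["U"] = np.concatenate(
            [_orthogonal(rng, H, H, dtype) for _ in range(3)], axis=1)  # h -> [z, r, c]
        self.params["b"] = np.zeros(3 * H, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        Uz, Ur, Uc = U[:, :H], U[:, H:2 * H], U[:, 2 * H:]
        h = np.zeros((B, H), dtype=W.dtype)
        cache = []
        ax_all = x.reshape(-1, D) @ W + b  # precompute input contributions
        ax_all = ax_all.reshape(B, T, 3 * H)
        for t in range(T):
            ax = ax_all[:, t]
            z = _sigmoid(ax[:, :H] + h @ Uz)
            r = _sigmoid(ax[:, H:2 * H] + h @ Ur)
            rh = r * h
            c = np.tanh(ax[:, 2 * H:] + rh @ Uc)
            h_new = (1.0 - z) * h + z * c
            cache.append((h, z, r, rh, c))
            h = h_new
        self._cache = cache
        self._x = x
        out = h
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            self._drop_mask = (self._rng.random(out.shape) < keep) / keep
            out = out * self._drop_mask.astype(out.dtype)
        else:
            self._drop_mask = None
        return out

    def backward(self, dh: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        Uz, Ur, Uc = U[:, :H], U[:, H:2 * H], U[:, 2 * H:]
        Wz, Wr, Wc = W[:, :H], W[:, H:2 * H], W[:, 2 * H:]
        if self._drop_mask is not None:
            dh = dh * self._drop_mask.astype(dh.dtype)
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = dh.astype(W.dtype).copy()
        for t in range(T - 1, -1, -1):
            h_prev, z, r, rh, c = self._cache[t]
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)
            dac = dc * (1.0 - c * c)
            drh = dac @ Uc.T
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            x_t = x[:, t]
            dW[:, :H] += x_t.T @ daz
            dW[:, H:2 * H] += x_t.T @ dar
            dW[:, 2 * H:] += x_t.T @ dac
            dU[:, :H] += h_prev.T @ daz
            dU[:, H:2 * H] += h_prev.T @ dar
            dU[:, 2 * H:] += rh.T @ dac
            db[:H] += daz.sum(axis=0)
            db[H:2 * H] += dar.sum(axis=0)
            db[2 * H:] += dac.sum(axis=0)
            dx[:, t] = daz @ Wz.T + dar @ Wr.T + dac @ Wc.T
            dh_prev += daz @ Uz.T + dar @ Ur.T
            dh = dh_prev
        self.grads["W"], self.grads["U"], self.grads["b"] = dW, dU, db
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    """Affine layer; the softmax of the final head lives in the loss."""

    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot(rng, (in_dim, out_dim), in_dim, out_dim, dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Model:
    """A plain sequential stack with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer], l2: float = 0.0) -> None:
        self.layers = layers
        self.l2 = l2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, train=False)
        return softmax(logits)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray,
                      train: bool = True) -> tuple[float, float]:
        """One forward/backward pass; returns (loss, accuracy).

        The loss is mean cross-entropy plus ``0.5 * l2 * sum(w**2)`` over
        weight matrices (biases are not decayed); gradients are left in
        each layer's ``grads``.
        """
        logits = self.forward(x, train=train)
        probs = softmax(logits)
        B = x.shape[0]
        eps = np.finfo(probs.dtype).tiny
        ce = -float(np.mean(np.log(probs[np.arange(B), y] + eps)))
        acc = float(np.mean(probs.argmax(axis=1) == y))
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        dy = (probs - onehot) / B
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        reg = 0.0
        for layer in self.layers:
            for name, p in layer.params.items():
                if name[0] in "WU":
                    reg += float(np.sum(p.astype(np.float64) ** 2))
                    layer.grads[name] = layer.grads[name] + self.l2 * p
        return ce + 0.5 * self.l2 * reg, acc

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, model: Model, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for layer, m, v in zip(self.model.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= (self.lr * (m[k] / corr1)
                      / (np.sqrt(v[k] / corr2) + self.eps)).astype(p.dtype)
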