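"""Minimal NumPy neural-network engine for the ranking model.

A deliberately small, dependency-free stack: 3x3 same-padding convolutions
via im2col, ReLU, 2x2 max pooling, global average pooling and a linear head,
trained with Adam.  Everything is float32 and fully deterministic for a
fixed seed (no threading-order effects; BLAS matmuls are reduction-order
stable for fixed shapes).

This exists because the scoring model is the package's core and the target
environment provides no deep-learning framework; at the tile sizes used
(64-128 px) CPU NumPy is entirely adequate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "GlobalAvgPool", "Linear", "Sequential", "Adam"]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, same padding, He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, h*w, c*k*k)
        return np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self._cache = (cols, (n, c, h, w))
        out = cols @ self.params["W"].T + self.params["b"]
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.k, self.k // 2
        d = dout.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (n, hw, c_out)
        d2 = np.ascontiguousarray(d).reshape(-1, self.c_out)
        self.grads["W"] = (d2.T @ cols.reshape(-1, cols.shape[2])).astype(np.float32)
        self.grads["b"] = d2.sum(axis=0).astype(np.float32)
        dcols = d @ self.params["W"]  # (n, hw, c*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        mask = xr == out[:, :, :, None, :, None]
        # distribute between tied maxima so the gradient mass is conserved
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        d = mask * dout[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = xr.shape
        return d.reshape(n, c, h2 * 2, w2 * 2).astype(np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = (rng.standard_normal((d_out, d_in)) * np.sqrt(1.0 / d_in)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dout.T @ self._x).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self.layers for name in l.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": l.params[name]
                for i, l in enumerate(self.layers) for name in l.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            for name in l.params:
                l.params[name] = np.asarray(state[f"{i}.{name}"], dtype=np.float32)


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers}

    def step(self) -> None:
        self.t += 1
        for layer, name in self.model.parameters():
            g = layer.grads[name]
            m = self.m[id(layer)][name]
            v = self.v[id(layer)][name]
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
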