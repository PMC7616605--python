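"""Minimal dense/convolutional network machinery on numpy.

Implements exactly what the autofocus Q-networks need — dense and strided
3x3 convolution layers with ReLU, global average pooling, smooth-L1 (Huber)
loss, RMSProp, EMA weight tracking and global-norm gradient clipping — with
explicit forward/backward passes.  Single-threaded use: each layer caches
its last forward inputs for the backward pass.

All weight initialisation is He-scaled and driven by an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Conv2d",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "smooth_l1",
    "RMSProp",
    "ema_update",
    "clip_grad_norm",
    "make_q_network",
    "make_encoder",
]


class Layer:
    """Base layer: ``params`` and matching ``grads`` dictionaries."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self._x: np.ndarray | None = None

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        self.grads = {"W": x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Conv2d(Layer):
    """3x3 (or kxk) convolution via im2col; NCHW layout, zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
    ):
        super().__init__()
        self.k, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)),
            "b": np.zeros(c_out),
        }

    def _im2col(self, xp: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        win = win[:, :, :h_out, :w_out]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(
            xp.shape[0], self.c_in * k * k, h_out * w_out
        )
        return cols

    def forward(self, x):
        b, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        h_out = (h + 2 * p - k) // s + 1
        w_out = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, h_out, w_out)
        out = np.einsum("of,bfl->bol", self.params["W"], cols) + self.params[
            "b"
        ].reshape(1, -1, 1)
        self._cache = (x.shape, xp.shape, cols, h_out, w_out)
        return out.reshape(b, self.c_out, h_out, w_out)

    def backward(self, dout):
        x_shape, xp_shape, cols, h_out, w_out = self._cache
        b = x_shape[0]
        k, s, p = self.k, self.stride, self.pad
        dflat = dout.reshape(b, self.c_out, h_out * w_out)
        self.grads = {
            "W": np.einsum("bol,bfl->of", dflat, cols),
            "b": dflat.sum(axis=(0, 2)),
        }
        dcols = np.einsum("of,bol->bfl", self.params["W"], dflat)
        dcols = dcols.reshape(b, self.c_in, k, k, h_out, w_out)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h_out * s : s, j : j + w_out * s : s] += dcols[
                    :, :, i, j
                ]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params.values()]

    def gradients(self) -> list[np.ndarray]:
        return [l.grads[name] for l in self.layers for name in l.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": layer.params[name]
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                arr = np.asarray(state[f"{i}.{name}"], dtype=float)
                if arr.shape != layer.params[name].shape:
                    raise ValueError(
                        f"shape mismatch for {i}.{name}: "
                        f"{arr.shape} vs {layer.params[name].shape}"
                    )
                layer.params[name] = arr.copy()

    def copy(self) -> "Sequential":
        import copy as _copy

        clone = _copy.deepcopy(self)
        return clone


def smooth_l1(pred: np.ndarray, target: np.ndarray, delta: float = 1.0):
    """Huber loss: mean value and gradient w.r.t. ``pred``."""
    diff = pred - target
    absd = np.abs(diff)
    quad = absd <= delta
    loss = np.where(quad, 0.5 * diff**2, delta * (absd - 0.5 * delta))
    grad = np.where(quad, diff, delta * np.sign(diff)) / diff.size
    return float(loss.mean()), grad


class RMSProp:
    """RMSProp: squared-gradient running average with decay ``rho``."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-5,
        rho: float = 0.95,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient/parameter count mismatch")
        for p, g, s in zip(self.params, grads, self.sq):
            s *= self.rho
            s += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


def ema_update(
    online: Iterable[np.ndarray] | Sequential,
    target: Iterable[np.ndarray] | Sequential,
    beta: float,
) -> list[np.ndarray]:
    """``target <- beta*online + (1-beta)*target``, elementwise, in place."""
    if isinstance(online, Sequential):
        online = online.parameters()
    if isinstance(target, Sequential):
        target = target.parameters()
    online, target = list(online), list(target)
    if len(online) != len(target):
        raise ValueError("weight list length mismatch")
    for o, t in zip(online, target):
        if o.shape != t.shape:
            raise ValueError(f"weight shape mismatch {o.shape} vs {t.shape}")
        t *= 1.0 - beta
        t += beta * o
    return target


def clip_grad_norm(grads: Sequence[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


def make_q_network(input_dim: int, rng: np.random.Generator) -> Sequential:
    """Q-value MLP: two hidden layers of 256 rectified units, 3 outputs."""
    return Sequential(
        [
            Dense(input_dim, 256, rng),
            ReLU(),
            Dense(256, 256, rng),
            ReLU(),
            Dense(256, 3, rng),
        ]
    )


def make_encoder(rng: np.random.Generator) -> Sequential:
    """Patch encoder: 4 stride-2 convolutions of 8 filters, 8-logit output.

    A 32x32 input maps through 16, 8, 4 to a 2x2x8 feature map, which is
    compressed to the 8 logits by spatial global averaging.
    """
    return Sequential(
        [
            Conv2d(1, 8, rng),
            ReLU(),
            Conv2d(8, 8, rng),
            ReLU(),
            Conv2d(8, 8, rng),
            ReLU(),
            Conv2d(8, 8, rng),
            GlobalAvgPool(),
        ]
    )
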