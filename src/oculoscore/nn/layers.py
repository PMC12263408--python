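"""Convolution / activation / upsampling layers and the SGD update."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator and momentum."""

    __slots__ = ("value", "grad", "vel", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.vel = np.zeros_like(value)
        self.decay = decay  # weight decay applies to kernels, not biases

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> List[Param]:
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2:]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, k, k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * k * k)
    return cols, ho, wo, (hp, wp)


class Conv2d(Layer):
    """k x k convolution, 'same'-style zero padding by default."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        bias: bool = True,
    ):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(w)
        self.b = Param(np.zeros(cout), decay=False) if bias else None
        self._cache: list = []

    def params(self) -> List[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        cols, ho, wo, padded = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.cout, -1)
        y = cols @ wmat.T
        if self.b is not None:
            y += self.b.value
        y = y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        self._cache.append((cols, x.shape, padded, ho, wo))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, (hp, wp), ho, wo = self._cache.pop()
        n, c, h, w = xshape
        dmat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.w.grad += (dmat.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.w.value.reshape(self.cout, -1)
        dcols = dcols.reshape(n, ho, wo, c, self.k, self.k)
        dxp = np.zeros((n, c, hp, wp))
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        p = self.pad
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def __init__(self) -> None:
        self._cache: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x > 0
        self._cache.append(mask)
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._cache.pop()


class Upsample2x(Layer):
    """Nearest-neighbour doubling of both spatial sides."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SGDMomentum:
    """Classical SGD with momentum and decoupled L2 weight decay."""

    def __init__(self, params: List[Param], momentum: float = 0.9, weight_decay: float = 5e-4):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            p.vel[...] = self.momentum * p.vel - lr * g
            p.value += p.vel
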