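"""Minimal NumPy neural-network engine for the density-regression U-Net.

Implements exactly the pieces the encoder/decoder architecture needs —
zero-padded ("same") convolutions via im2col + GEMM, 2x2 max pooling,
2x2 stride-2 transposed convolution, ReLU, skip concatenation — with
explicit forward/backward passes and an Adam optimizer. Single-image
batches; activations are ``(channels, H, W)`` arrays. float32 by default
(float64 is used by the gradient-check tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2D", "ReLU", "MaxPool2", "UpConv2", "UNet", "Adam"]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv2D:
    """k x k convolution with zero padding (output size = input size)."""

    def __init__(self, in_c: int, out_c: int, ksize: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = in_c * ksize * ksize
        # He initialization, appropriate for ReLU nonlinearities
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, fan_in))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_c, dtype=dtype))
        self.in_c, self.out_c, self.k = in_c, out_c, ksize
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, pad = self.k, self.k // 2
        if pad:
            xp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
            xp[:, pad:-pad, pad:-pad] = x
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (c, h, w, k, k) -> (c*k*k, h*w)
        return np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(c * k * k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = self._im2col(x)
        y = self.W.value @ cols + self.b.value[:, None]
        self._cache = (cols, (c, h, w))
        return y.reshape(self.out_c, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (c, h, w) = self._cache
        k, pad = self.k, self.k // 2
        dyf = dy.reshape(self.out_c, h * w)
        self.W.grad += dyf @ cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = (self.W.value.T @ dyf).reshape(c, k, k, h, w)
        if pad == 0:
            return dcols[:, 0, 0]
        dxp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w] += dcols[:, i, j]
        return dxp[:, pad:-pad, pad:-pad]


class ReLU:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool2:
    """2x2 max pooling, stride 2; requires even side lengths."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xv = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, h // 2, w // 2, 4
        )
        self._idx = xv.argmax(axis=-1)
        self._shape = (c, h, w)
        return np.take_along_axis(xv, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dxv = np.zeros((c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxv, self._idx[..., None], dy[..., None], axis=-1)
        return dxv.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


class UpConv2:
    """2x2 transposed convolution with stride 2 (doubles both sides)."""

    def __init__(self, in_c: int, out_c: int, *, rng: np.random.Generator, dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / in_c), size=(out_c, in_c, 2, 2))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_c, dtype=dtype))
        self.out_c = out_c

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        self._xf = x.reshape(c, h * w)
        # (o, c, a, b) -> (o*a*b, c) so the whole op is one GEMM
        wm = np.ascontiguousarray(self.W.value.transpose(0, 2, 3, 1)).reshape(-1, c)
        t = (wm @ self._xf).reshape(self.out_c, 2, 2, h, w)
        y = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2)).reshape(
            self.out_c, 2 * h, 2 * w
        )
        return y + self.b.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = self.W.value.shape[1]
        h2, w2 = dy.shape[1:]
        h, w = h2 // 2, w2 // 2
        dt = np.ascontiguousarray(
            dy.reshape(self.out_c, h, 2, w, 2).transpose(0, 2, 4, 1, 3)
        ).reshape(self.out_c * 4, h * w)
        dwm = dt @ self._xf.T  # (o*a*b, c)
        self.W.grad += dwm.reshape(self.out_c, 2, 2, c).transpose(0, 3, 1, 2)
        self.b.grad += dy.sum(axis=(1, 2))
        wm = np.ascontiguousarray(self.W.value.transpose(0, 2, 3, 1)).reshape(-1, c)
        return (wm.T @ dt).reshape(c, h, w)


class UNet:
    """Half-width U-Net density regressor.

    ``depth`` max-pooling levels (default 4) with filter counts
    ``base_filters * 2**level`` on the encoding path, mirrored on the
    decoding path with skip concatenations; all convolutions are padded
    3x3 so the output matches the input size; the 1x1 head uses a ReLU
    so predicted densities are nonnegative. Input sides must be divisible
    by ``2**depth``.
    """

    def __init__(self, base_filters: int = 32, depth: int = 4, in_channels: int = 1,
                 *, seed: int = 0, dtype=np.float32):
        self.base_filters = base_filters
        self.depth = depth
        self.in_channels = in_channels
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = [base_filters * 2**level for level in range(depth + 1)]
        mk = lambda ic, oc, k=3: Conv2D(ic, oc, k, rng=rng, dtype=dtype)
        self.enc = []
        ic = in_channels
        for level in range(depth + 1):  # last one is the bottleneck
            self.enc.append([mk(ic, f[level]), ReLU(), mk(f[level], f[level]), ReLU()])
            ic = f[level]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups, self.dec = [], []
        for level in range(depth - 1, -1, -1):
            self.ups.append(UpConv2(f[level + 1], f[level], rng=rng, dtype=dtype))
            self.dec.append([mk(2 * f[level], f[level]), ReLU(), mk(f[level], f[level]), ReLU()])
        self.head = mk(f[0], 1, 1)
        self.head_relu = ReLU()

    # -- plumbing ---------------------------------------------------------
    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.pools
        for up, block in zip(self.ups, self.dec):
            yield up
            yield from block
        yield self.head
        yield self.head_relu

    @property
    def params(self) -> list[Param]:
        return [p for layer in self._layers() for p in layer.params]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (H, W) or (C, H, W) -> (H, W) density prediction."""
        if x.ndim == 2:
            x = x[None]
        x = x.astype(self.dtype, copy=False)
        h, w = x.shape[1:]
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"input sides must be divisible by {2 ** self.depth}, got {(h, w)}"
            )
        skips = []
        for level in range(self.depth):
            for layer in self.enc[level]:
                x = layer.forward(x)
            skips.append(x)
            x = self.pools[level].forward(x)
        for layer in self.enc[self.depth]:
            x = layer.forward(x)
        self._skip_channels = []
        for up, block in zip(self.ups, self.dec):
            x = up.forward(x)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            for layer in block:
                x = layer.forward(x)
        x = self.head.forward(x)
        x = self.head_relu.forward(x)
        return x[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); accumulates parameter grads."""
        g = dy[None].astype(self.dtype, copy=False)
        g = self.head_relu.backward(g)
        g = self.head.backward(g)
        skip_grads = []
        for i in range(self.depth - 1, -1, -1):
            up, block = self.ups[i], self.dec[i]
            for layer in reversed(block):
                g = layer.backward(g)
            nskip = self._skip_channels[i]
            skip_grads.append(g[:nskip])
            g = up.backward(g[nskip:])
        for layer in reversed(self.enc[self.depth]):
            g = layer.backward(g)
        for level in range(self.depth - 1, -1, -1):
            g = self.pools[level].backward(g)
            g = g + skip_grads[level]
            for layer in reversed(self.enc[level]):
                g = layer.backward(g)
        return g

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=self.dtype)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value[...] = arr


class Adam:
    """Adam optimizer with the standard (framework-default) moments."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
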