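"""NumPy neural-network layers with explicit forward/backward passes.

All layers operate on NCHW float32/float64 arrays and cache whatever the
backward pass needs.  ``train`` mode affects only batch normalization
(batch statistics vs frozen running statistics); everything else is
deterministic, so evaluation-mode forwards are bit-reproducible.

Parameters are exposed as :class:`Param` objects (value + gradient) so a
single optimizer can walk the whole network.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "BilinearUp2",
    "Sigmoid",
]


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


_OFFSETS = [(i, j) for i in range(3) for j in range(3)]


class Conv2d:
    """2D convolution, kernel 3x3 (padding 1) or 1x1, stride 1.

    The 3x3 path assembles im2col columns channel-last with nine slice
    copies (fast, contiguous writes) and runs one matmul; its backward
    scatters the column gradient back with nine shifted adds.  Weight
    layout is (out_channels, 9 * in_channels) with offset-major columns.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv",
                 needs_input_grad: bool = True) -> None:
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * kernel * kernel
        w = rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)
        self.weight = Param(w.astype(np.float32), f"{name}.weight")
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        if self.k == 1:
            col = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
            out = col @ self.weight.value.T + self.bias.value
            self._cache = (col, x.shape) if train else None
            return np.ascontiguousarray(
                out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)
            )
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        xpt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))
        out = np.empty((n, h, w, self.cout), dtype=x.dtype)
        out[...] = self.bias.value
        wv = self.weight.value
        for kk, (i, j) in enumerate(_OFFSETS):
            wk = wv[:, kk * c : (kk + 1) * c].T  # (cin, cout)
            out += xpt[:, i : i + h, j : j + w, :] @ wk
        self._cache = (xpt, x.shape) if train else None
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, gout: np.ndarray) -> np.ndarray | None:
        cache, (n, c, h, w) = self._cache
        gnhwc = np.ascontiguousarray(gout.transpose(0, 2, 3, 1))
        g2 = gnhwc.reshape(-1, self.cout)
        self.bias.grad += g2.sum(axis=0)
        if self.k == 1:
            col = cache
            self.weight.grad += g2.T @ col
            if not self.needs_input_grad:
                return None
            gcol = g2 @ self.weight.value
            return np.ascontiguousarray(
                gcol.reshape(n, h, w, c).transpose(0, 3, 1, 2)
            )
        xpt = cache
        wv = self.weight.value
        gxpt = (
            np.zeros((n, h + 2, w + 2, c), dtype=gout.dtype)
            if self.needs_input_grad
            else None
        )
        for kk, (i, j) in enumerate(_OFFSETS):
            view = xpt[:, i : i + h, j : j + w, :].reshape(-1, c)
            self.weight.grad[:, kk * c : (kk + 1) * c] += g2.T @ view
            if gxpt is not None:
                wk = wv[:, kk * c : (kk + 1) * c]  # (cout, cin)
                gxpt[:, i : i + h, j : j + w, :] += gnhwc @ wk
        if gxpt is None:
            return None
        return np.ascontiguousarray(
            gxpt[:, 1 : 1 + h, 1 : 1 + w, :].transpose(0, 3, 1, 2)
        )


class BatchNorm2d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.c = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma.value[None, :, None, None]
        # standard batchnorm backward over the (N, H, W) population
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (gxhat - s1 / n_eff - xhat * s2 / n_eff)


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2; requires even spatial dims."""

    def __init__(self) -> None:
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=gout.dtype)
        np.put_along_axis(gflat, idx[..., None], gout[..., None], axis=-1)
        return (
            gflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class BilinearUp2:
    """Bilinear 2x upsampling as two separable linear maps.

    The interpolation matrix maps output pixel i to source coordinate
    (i + 0.5) / 2 - 0.5 with edge clamping; the backward pass is the
    transpose of the same linear map.
    """

    _matrices: dict[int, np.ndarray] = {}

    def __init__(self) -> None:
        self._cache = None

    def params(self):
        return []

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        u = cls._matrices.get(n)
        if u is None:
            u = np.zeros((2 * n, n), dtype=np.float32)
            src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
            i0 = np.clip(np.floor(src).astype(int), 0, n - 1)
            i1 = np.clip(i0 + 1, 0, n - 1)
            frac = np.clip(src - np.floor(src), 0.0, 1.0)
            frac[src < 0] = 0.0
            frac[src > n - 1] = 0.0
            rows = np.arange(2 * n)
            u[rows, i0] += 1.0 - frac
            u[rows, i1] += frac
            cls._matrices[n] = u
        return u

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        uh, uw = self._matrix(h), self._matrix(w)
        out = np.einsum("ph,nchw->ncpw", uh, x, optimize=True)
        out = np.einsum("qw,ncpw->ncpq", uw, out, optimize=True)
        if train:
            self._cache = (h, w)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, w = self._cache
        uh, uw = self._matrix(h), self._matrix(w)
        g = np.einsum("qw,ncpq->ncpw", uw, gout, optimize=True)
        return np.einsum("ph,ncpw->nchw", uh, g, optimize=True)


class Sigmoid:
    def __init__(self) -> None:
        self._out = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # clip before exp: sigmoid saturates beyond +-60 anyway and the
        # clip avoids float32 overflow warnings on extreme logits
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        if train:
            self._out = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._out * (1.0 - self._out)
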