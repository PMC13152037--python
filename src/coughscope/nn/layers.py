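"""Minimal NumPy neural-network layers with explicit backpropagation.

Each layer caches what its backward pass needs during ``forward`` and
returns input gradients from ``backward``. Arrays are NCHW float32;
convolution is im2col + BLAS matmul, its input gradient is the standard
9-slice col2im accumulation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self) -> list[Param]:
        return []

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Param]]:
        out = []
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                out.append((f"{prefix}{name}", attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_parameters(f"{prefix}{name}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad.fill(0.0)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, pad_value: float = 0.0):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
    else:
        xp = x
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, c, oh, ow, kh, kw) -> (n*oh*ow, c*kh*kw)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(col), oh, ow


def _col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int, oh: int, ow: int):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    d = dcol.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Module):
    """2D convolution (cross-correlation), no bias (a BatchNorm follows)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng()
        # He initialization, fan-out mode with ReLU gain
        fan_out = kernel * kernel * out_ch
        std = np.sqrt(2.0 / fan_out)
        self.weight = Param(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self._cache = None

    def parameters(self):
        return [self.weight]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        col, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = col @ wmat.T
        out = out.reshape(x.shape[0], oh, ow, self.out_ch).transpose(0, 3, 1, 2)
        self._cache = (col, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, x_shape, oh, ow = self._cache
        n = x_shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.weight.grad += (dmat.T @ col).reshape(self.weight.value.shape)
        dcol = dmat @ self.weight.value.reshape(self.out_ch, -1)
        return _col2im(dcol, x_shape, self.kernel, self.kernel, self.stride, self.pad, oh, ow)


class BatchNorm2d(Module):
    """Batch normalization with EMA running statistics for inference.

    Also supports a "precise" re-estimation mode: between
    :meth:`start_stats_accumulation` and :meth:`finish_stats_accumulation`
    train-mode forwards average batch statistics instead of EMA-updating
    them, so inference statistics can be recomputed under the final
    weights (important when training runs for only a few steps).
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None
        self._accumulating = False

    def parameters(self):
        return [self.gamma, self.beta]

    def start_stats_accumulation(self) -> None:
        self._accumulating = True
        self._acc_mean = np.zeros_like(self.running_mean, dtype=np.float64)
        self._acc_var = np.zeros_like(self.running_var, dtype=np.float64)
        self._acc_count = 0

    def finish_stats_accumulation(self) -> None:
        if self._acc_count > 0:
            self.running_mean = (self._acc_mean / self._acc_count).astype(np.float32)
            self.running_var = (self._acc_var / self._acc_count).astype(np.float32)
        self._accumulating = False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._accumulating:
                self._acc_mean += mean
                self._acc_var += var
                self._acc_count += 1
            else:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not train:
            return dout * g
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dmean = dout.mean(axis=(0, 2, 3))[None, :, None, None]
        dvar = (dout * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (dout - dmean - xhat * dvar)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.kernel
        # -inf padding so padded positions never win the max
        col, oh, ow = _im2col(x, k, k, self.stride, self.pad, pad_value=-np.inf)
        n, c = x.shape[0], x.shape[1]
        win = col.reshape(n * oh * ow, c, k * k)
        arg = win.argmax(axis=2)
        out = np.take_along_axis(win, arg[:, :, None], axis=2)[:, :, 0]
        self._cache = (arg, x.shape, oh, ow)
        return out.reshape(n, oh, ow, c).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, x_shape, oh, ow = self._cache
        k = self.kernel
        n, c = x_shape[0], x_shape[1]
        dwin = np.zeros((n * oh * ow, c, k * k), dtype=dout.dtype)
        d = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, c)
        np.put_along_axis(dwin, arg[:, :, None], d[:, :, None], axis=2)
        dcol = dwin.reshape(n * oh * ow, c * k * k)
        return _col2im(dcol, x_shape, k, k, self.stride, self.pad, oh, ow)


class GlobalAvgPool2d(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_dim)  # He, fan-in
        self.weight = Param(rng.normal(0.0, std, (out_dim, in_dim)))
        self.bias = Param(np.zeros(out_dim))
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value
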