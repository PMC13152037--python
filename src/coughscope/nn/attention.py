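"""Channel attention: per-channel gating of feature maps.

Spatial global max- and average-pooling squeeze an H x W x C feature map
to two C-vectors; a shared multilayer perceptron maps each to C scores;
the sigmoid of their sum gives one weight in (0, 1) per channel, which
rescales the residual block output after the skip addition:

    M_c = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F)))
    Z   = M_c * (F(x) + x)

The shared MLP is C -> 256 -> ReLU -> 128 -> ReLU -> C by default.

Two APIs live here: plain functions on a single channel-last (H, W, C)
map (the algebraic contract, convenient to verify by hand), and the
batched NCHW :class:`ChannelAttention` module with backpropagation used
inside the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Linear, Module, Param

DEFAULT_HIDDEN_SIZES = (256, 128)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64 if x.dtype == np.float64 else np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def global_pool(feature_map: np.ndarray, mode: str) -> np.ndarray:
    """Squeeze an (H, W, C) map to a C-vector by spatial max or mean."""
    f = np.asarray(feature_map)
    if f.ndim != 3:
        raise ValueError("feature map must be H x W x C")
    if mode == "max":
        return f.max(axis=(0, 1))
    if mode == "avg":
        return f.mean(axis=(0, 1))
    raise ValueError(f"unknown pooling mode {mode!r}")


@dataclass
class CamMlpParams:
    """Weights of the shared perceptron: affine maps C -> h0 -> h1 -> C.

    ``layers`` is a list of (weight, bias) pairs, weight shaped
    (out_dim, in_dim). ReLU follows every layer except the last.
    """

    layers: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def channels(self) -> int:
        return self.layers[0][0].shape[1]

    @classmethod
    def init(cls, channels: int, hidden_sizes=DEFAULT_HIDDEN_SIZES,
             rng: np.random.Generator | None = None) -> "CamMlpParams":
        rng = rng or np.random.default_rng()
        dims = [channels, *hidden_sizes, channels]
        layers = []
        for din, dout in zip(dims[:-1], dims[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / din), (dout, din))
            layers.append((w, np.zeros(dout)))
        return cls(layers)

    @classmethod
    def zeros(cls, channels: int, hidden_sizes=DEFAULT_HIDDEN_SIZES) -> "CamMlpParams":
        dims = [channels, *hidden_sizes, channels]
        return cls([(np.zeros((dout, din)), np.zeros(dout)) for din, dout in zip(dims[:-1], dims[1:])])


def _mlp_apply(params: CamMlpParams, v: np.ndarray) -> np.ndarray:
    h = v
    last = len(params.layers) - 1
    for i, (w, b) in enumerate(params.layers):
        h = h @ w.T + b
        if i < last:
            h = np.maximum(h, 0.0)
    return h


def channel_attention(feature_map: np.ndarray, params: CamMlpParams) -> np.ndarray:
    """Channel weights M_c(F) in (0, 1) for one (H, W, C) feature map."""
    f = np.asarray(feature_map)
    if f.ndim != 3:
        raise ValueError("feature map must be H x W x C")
    if f.shape[2] != params.channels:
        raise ValueError(
            f"MLP expects {params.channels} channels, feature map has {f.shape[2]}")
    avg = global_pool(f, "avg")
    mx = global_pool(f, "max")
    return sigmoid(_mlp_apply(params, avg) + _mlp_apply(params, mx))


def apply_attention(f_out: np.ndarray, x_skip: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Z[h, w, c] = weights[c] * (f_out[h, w, c] + x_skip[h, w, c])."""
    f_out = np.asarray(f_out)
    x_skip = np.asarray(x_skip)
    if f_out.shape != x_skip.shape:
        raise ValueError(f"shape mismatch: {f_out.shape} vs {x_skip.shape}")
    weights = np.asarray(weights)
    if weights.shape != (f_out.shape[2],):
        raise ValueError("weights length must equal the channel count")
    return weights[None, None, :] * (f_out + x_skip)


class ChannelAttention(Module):
    """Batched NCHW channel-attention module with a shared three-layer MLP."""

    def __init__(self, channels: int, hidden_sizes=DEFAULT_HIDDEN_SIZES,
                 rng: np.random.Generator | None = None):
        self.channels = channels
        dims = [channels, *hidden_sizes, channels]
        self.fcs = [Linear(din, dout, rng) for din, dout in zip(dims[:-1], dims[1:])]
        self._cache = None

    def parameters(self):
        return [p for fc in self.fcs for p in fc.parameters()]

    def _mlp_forward(self, v: np.ndarray):
        acts = []  # per-layer (input, relu mask or None)
        h = v
        last = len(self.fcs) - 1
        for i, fc in enumerate(self.fcs):
            x_in = h
            h = x_in @ fc.weight.value.T + fc.bias.value
            mask = None
            if i < last:
                mask = h > 0
                h = h * mask
            acts.append((x_in, mask))
        return h, acts

    def _mlp_backward(self, dout: np.ndarray, acts) -> np.ndarray:
        d = dout
        for i in range(len(self.fcs) - 1, -1, -1):
            x_in, _ = acts[i]
            fc = self.fcs[i]
            fc.weight.grad += d.T @ x_in
            fc.bias.grad += d.sum(axis=0)
            d = d @ fc.weight.value
            if i > 0:
                prev_mask = acts[i - 1][1]
                d = d * prev_mask
        return d

    def forward(self, f: np.ndarray, train: bool = True) -> np.ndarray:
        """f: (N, C, H, W) -> channel weights (N, C)."""
        n, c, h, w = f.shape
        flat = f.reshape(n, c, h * w)
        avg = flat.mean(axis=2)
        arg = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]
        a_out, a_acts = self._mlp_forward(avg)
        m_out, m_acts = self._mlp_forward(mx)
        weights = sigmoid(a_out + m_out)
        self._cache = (f.shape, arg, a_acts, m_acts, weights)
        return weights

    def backward(self, dweights: np.ndarray) -> np.ndarray:
        shape, arg, a_acts, m_acts, weights = self._cache
        n, c, h, w = shape
        ds = dweights * weights * (1.0 - weights)
        davg = self._mlp_backward(ds, a_acts)
        dmx = self._mlp_backward(ds, m_acts)
        df = np.zeros((n, c, h * w), dtype=dweights.dtype)
        df += (davg / (h * w))[:, :, None]
        np.put_along_axis(
            df, arg[:, :, None],
            np.take_along_axis(df, arg[:, :, None], axis=2) + dmx[:, :, None],
            axis=2,
        )
        return df.reshape(shape)

    # --- interop with the functional API -------------------------------
    def to_params(self) -> CamMlpParams:
        return CamMlpParams([(fc.weight.value.astype(np.float64), fc.bias.value.astype(np.float64))
                             for fc in self.fcs])

    def load_params(self, params: CamMlpParams) -> None:
        for fc, (w, b) in zip(self.fcs, params.layers):
            fc.weight.value = np.asarray(w, dtype=np.float32)
            fc.bias.value = np.asarray(b, dtype=np.float32)
            fc.weight.grad = np.zeros_like(fc.weight.value)
            fc.bias.grad = np.zeros_like(fc.bias.value)
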