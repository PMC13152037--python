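"""The 18-layer residual network with channel attention in every block.

Architecture: a 7x7/stride-2 stem to 64 channels, 3x3/stride-2 max
pooling, four stages of two basic blocks with [64, 128, 256, 512]
channels (the first block of stages 2-4 downsamples with a stride-2
1x1 projection skip), global average pooling, and a fully connected
classifier. Each basic block is conv-BN-ReLU-conv-BN; channel-attention
weights are computed from the block output and applied after the skip
addition (``Z = M_c * (F(x) + x)``), followed by ReLU. Disabling
attention recovers the plain residual network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .attention import DEFAULT_HIDDEN_SIZES, ChannelAttention
from .layers import BatchNorm2d, Conv2d, GlobalAvgPool2d, Linear, MaxPool2d, Module, ReLU


@dataclass
class NetworkConfig:
    num_classes: int = 5
    input_channels: int = 1
    input_size: int = 224
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    attention_enabled: bool = True
    attention_position: str = "post_sum"  # or "pre_sum"
    cam_hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN_SIZES
    batch_norm: bool = True

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.attention_position not in ("post_sum", "pre_sum"):
            raise ValueError(f"unknown attention_position {self.attention_position!r}")
        if len(self.stage_channels) == 0 or any(c < 1 for c in self.stage_channels):
            raise ValueError("invalid stage_channels")

    def to_dict(self) -> dict:
        return {
            "num_classes": self.num_classes,
            "input_channels": self.input_channels,
            "input_size": self.input_size,
            "stage_channels": list(self.stage_channels),
            "blocks_per_stage": self.blocks_per_stage,
            "attention_enabled": self.attention_enabled,
            "attention_position": self.attention_position,
            "cam_hidden_sizes": list(self.cam_hidden_sizes),
            "batch_norm": self.batch_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("stage_channels", "cam_hidden_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class _Identity(Module):
    def forward(self, x, train=True):
        return x

    def backward(self, dout):
        return dout


class BasicBlock(Module):
    """conv-BN-ReLU-conv-BN, attention-gated residual sum, ReLU."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        bn = BatchNorm2d if cfg.batch_norm else (lambda c: _Identity())
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng)
        self.bn1 = bn(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng)
        self.bn2 = bn(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride, 0, rng)
            self.down_bn = bn(out_ch)
            self.downsample = True
        self.attention = None
        if cfg.attention_enabled:
            self.attention = ChannelAttention(out_ch, cfg.cam_hidden_sizes, rng)
        self.attention_position = cfg.attention_position
        self.relu_out = ReLU()
        self._cache = None
        self.force_unit_attention = False  # ablation probe: M_c == 1

    def parameters(self):
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.downsample:
            ps += self.down_conv.parameters() + self.down_bn.parameters()
        if self.attention is not None:
            ps += self.attention.parameters()
        return ps

    def forward(self, x, train=True):
        f = self.conv1.forward(x, train)
        f = self.bn1.forward(f, train)
        f = self.relu1.forward(f, train)
        f = self.conv2.forward(f, train)
        f = self.bn2.forward(f, train)
        if self.downsample:
            skip = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            skip = x
        mc = None
        if self.attention is not None and not self.force_unit_attention:
            mc = self.attention.forward(f, train)
            mcb = mc[:, :, None, None]
            if self.attention_position == "post_sum":
                z = mcb * (f + skip)
            else:
                z = mcb * f + skip
        else:
            z = f + skip
        self._cache = (f, skip, mc)
        return self.relu_out.forward(z, train)

    def backward(self, dout):
        f, skip, mc = self._cache
        dz = self.relu_out.backward(dout)
        if mc is not None:
            mcb = mc[:, :, None, None]
            if self.attention_position == "post_sum":
                dmc = (dz * (f + skip)).sum(axis=(2, 3))
                dsum = dz * mcb
                df, dskip = dsum, dsum.copy()
            else:
                dmc = (dz * f).sum(axis=(2, 3))
                df, dskip = dz * mcb, dz.copy()
            df = df + self.attention.backward(dmc)
        else:
            df, dskip = dz, dz.copy()
        d = self.bn2.backward(df)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.conv1.backward(d)
        if self.downsample:
            dx = dx + self.down_conv.backward(self.down_bn.backward(dskip))
        else:
            dx = dx + dskip
        return dx


class CamResNet18(Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        bn = BatchNorm2d if cfg.batch_norm else (lambda c: _Identity())
        c0 = cfg.stage_channels[0]
        self.stem_conv = Conv2d(cfg.input_channels, c0, 7, 2, 3, rng)
        self.stem_bn = bn(c0)
        self.stem_relu = ReLU()
        self.maxpool = MaxPool2d(3, 2, 1)
        self.blocks: list[BasicBlock] = []
        in_ch = c0
        for si, ch in enumerate(cfg.stage_channels):
            for bi in range(cfg.blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                self.blocks.append(BasicBlock(in_ch, ch, stride, cfg, rng))
                in_ch = ch
        self.gap = GlobalAvgPool2d()
        self.fc = Linear(in_ch, cfg.num_classes, rng)

    def parameters(self):
        ps = self.stem_conv.parameters() + self.stem_bn.parameters()
        for b in self.blocks:
            ps += b.parameters()
        return ps + self.fc.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, C, H, W) float32 -> logits (N, num_classes)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = self.stem_conv.forward(x, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        h = self.maxpool.forward(h, train)
        for b in self.blocks:
            h = b.forward(h, train)
        h = self.gap.forward(h, train)
        return self.fc.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc.backward(dlogits.astype(np.float32))
        d = self.gap.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.maxpool.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        return self.stem_conv.backward(d)

    def set_force_unit_attention(self, flag: bool) -> None:
        for b in self.blocks:
            b.force_unit_attention = flag

    # --- serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value for name, p in self.named_parameters()}

        def add_buffers(mod: Module, prefix: str):  # batch-norm running stats

            for name, attr in vars(mod).items():
                if isinstance(attr, BatchNorm2d):
                    state[f"{prefix}{name}.running_mean"] = attr.running_mean
                    state[f"{prefix}{name}.running_var"] = attr.running_var
                elif isinstance(attr, Module):
                    add_buffers(attr, f"{prefix}{name}.")
                elif isinstance(attr, (list, tuple)):
                    for i, item in enumerate(attr):
                        if isinstance(item, Module):
                            add_buffers(item, f"{prefix}{name}.{i}.")
        add_buffers(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        for key, val in state.items():
            if key.endswith(".running_mean") or key.endswith(".running_var"):
                continue
            named[key].value = np.asarray(val, dtype=np.float32)
            named[key].grad = np.zeros_like(named[key].value)

        def load_buffers(mod: Module, prefix: str):
            for name, attr in vars(mod).items():
                if isinstance(attr, BatchNorm2d):
                    attr.running_mean = np.asarray(state[f"{prefix}{name}.running_mean"], dtype=np.float32)
                    attr.running_var = np.asarray(state[f"{prefix}{name}.running_var"], dtype=np.float32)
                elif isinstance(attr, Module):
                    load_buffers(attr, f"{prefix}{name}.")
                elif isinstance(attr, (list, tuple)):
                    for i, item in enumerate(attr):
                        if isinstance(item, Module):
                            load_buffers(item, f"{prefix}{name}.{i}.")
        load_buffers(self, "")

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))


def build_cam_resnet18(cfg: NetworkConfig | None = None, seed: int = 0) -> CamResNet18:
    """Construct the network with He-initialized weights from ``seed``."""
    cfg = cfg or NetworkConfig()
    rng = np.random.default_rng(seed)
    return CamResNet18(cfg, rng)


def iter_batchnorms(mod: Module):
    for attr in vars(mod).values():
        if isinstance(attr, BatchNorm2d):
            yield attr
        elif isinstance(attr, Module):
            yield from iter_batchnorms(attr)
        elif isinstance(attr, (list, tuple)):
            for item in attr:
                if isinstance(item, Module):
                    yield from iter_batchnorms(item)


def recalibrate_batchnorm(model: "CamResNet18", x: np.ndarray,
                          batch_size: int = 32, max_batches: int = 16,
                          seed: int = 0) -> None:
    """Re-estimate BN inference statistics under the current weights.

    Runs up to ``max_batches`` train-mode forward passes over (a random
    subset of) ``x`` and replaces the running statistics with the average
    of the observed batch statistics ("precise" BN). Short training runs
    move the weights far faster than the EMA statistics can follow; this
    makes inference-mode behaviour match the final weights.
    """
    n = len(x)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    bns = list(iter_batchnorms(model))
    for bn in bns:
        bn.start_stats_accumulation()
    used = 0
    for i in range(0, n, batch_size):
        if used >= max_batches:
            break
        idx = order[i : i + batch_size]
        if len(idx) < 2:
            break
        model.forward(x[idx], train=True)
        used += 1
    for bn in bns:
        bn.finish_stats_accumulation()


def softmax_scores(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis; rejects non-finite input."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def save_checkpoint(path: str, model: CamResNet18, meta: dict | None = None) -> None:
    """Single-archive checkpoint: weights + config + metadata (NPZ)."""
    state = model.state_dict()
    payload = {f"param/{k}": v for k, v in state.items()}
    header = {"format_version": 1, "config": model.cfg.to_dict(), "meta": meta or {}}
    payload["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str) -> tuple[CamResNet18, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"].tobytes()).decode())
        cfg = NetworkConfig.from_dict(header["config"])
        model = build_cam_resnet18(cfg, seed=0)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model, header.get("meta", {})
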