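"""The CATM network: cross-scale attention CNN + Bi-LSTM classifier.

Input is a sequence of fused feature frames (planes x 8 x 9 per 0.5 s
window).  A 1x1 stem convolution lifts the planes to the working width,
then each block runs the cross-scale attention module (CSAM: parallel
1x1 / 3x3 / 5x5 convolutions plus a 3x3 max pool, concatenated, gated by
frequency-space attention) followed by a feature transition module (FTM:
batch norm, 1x1 channel reduction, 3x3 same-padding max pool).  Frame
maps are flattened, projected, run through a bidirectional LSTM over the
window sequence, fused to the classifier width, and classified by a deep
three-layer head with dropout.

Default sizes reproduce the published parameter budget of 9,478,504
trainable scalars exactly (see ``docs/methods.md`` for how the sizes the
architecture tables leave open were pinned down).

Ablation builds mirror the published module-ablation protocol:

* ``use_csam=False``  — no convolutional blocks (Model 1);
* ``use_fsam=False``  — attention multipliers fixed at 1 (Model 2);
* ``use_bilstm=False``— temporal mean over per-frame projections (Model 3);
* ``use_dcm=False``   — single linear classification layer (Model 4);
* ``single_scale=k``  — one k x k convolution instead of the cross-scale
  branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

__all__ = ["ModelConfig", "CATM", "build", "count_params", "save_weights", "load_weights"]


class ConfigError(ValueError):
    """Architecture hyperparameters violate an invariant."""


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters.  Defaults are the full model."""

    in_planes: int = 16
    stem_width: int = 80
    branch_width: int = 128
    n_blocks: int = 2
    attention_reduction: int = 8
    spatial_kernel: int = 3
    proj_dim: int = 1414          # flattened frame -> Bi-LSTM input width
    lstm_hidden: int = 35         # per direction
    classifier_widths: tuple[int, int, int] = (128, 64, 32)
    n_classes: int = 2
    dropout: float = 0.5
    seq_len: int = 6              # 0.5 s windows per sample (3 s)
    grid: tuple[int, int] = (8, 9)
    # ablation switches
    use_csam: bool = True
    use_fsam: bool = True
    use_bilstm: bool = True
    use_dcm: bool = True
    single_scale: int | None = None

    @property
    def concat_width(self) -> int:
        if self.single_scale is not None:
            return self.branch_width
        return 3 * self.branch_width + self.stem_width

    def validate(self) -> None:
        if min(self.in_planes, self.stem_width, self.branch_width, self.proj_dim,
               self.lstm_hidden, self.n_classes, self.seq_len) <= 0:
            raise ConfigError("all widths and counts must be positive")
        if self.n_blocks < 1 and self.use_csam:
            raise ConfigError("need at least one block")
        if self.spatial_kernel % 2 == 0:
            raise ConfigError("spatial attention kernel must be odd")
        if self.single_scale is not None and self.single_scale % 2 == 0:
            raise ConfigError("single-scale kernel must be odd")
        if self.use_fsam and self.use_csam and self.concat_width % self.attention_reduction:
            raise ConfigError(
                f"attention_reduction {self.attention_reduction} must divide "
                f"the concatenated width {self.concat_width}"
            )
        if self.n_classes not in (2, 4):
            raise ConfigError("n_classes must be 2 or 4")

    @staticmethod
    def toy(in_planes: int = 16, n_classes: int = 2, seq_len: int = 6) -> "ModelConfig":
        """A small configuration for fast experiments and tests.

        Convolutional and recurrent widths shrink; the classifier keeps
        its full widths — it is computationally negligible, and dropout
        0.5 over very few units makes tiny heads collapse-prone (dead
        ReLUs) under aggressive optimization.
        """
        return ModelConfig(
            in_planes=in_planes,
            stem_width=8,
            branch_width=8,
            n_blocks=1,
            attention_reduction=8,
            proj_dim=64,
            lstm_hidden=16,
            classifier_widths=(128, 64, 32),
            n_classes=n_classes,
            seq_len=seq_len,
        )


class FSAM(nn.Module):
    """Frequency-space attention.

    Frequency: spatial global average per convolution channel, through a
    bottleneck MLP plus a standalone bias term, sigmoid-gated, multiplied
    into every location of its channel.  Space: channel-wise max map,
    through a small same-padding convolution, ReLU and sigmoid, broadcast
    over channels.  The most recent weight arrays are kept for inspection.
    """

    def __init__(self, channels: int, reduction: int, kernel: int, rng: np.random.Generator):
        if channels % reduction:
            raise ConfigError("reduction must divide the channel count")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)
        self.bias = nn.Tensor(np.zeros(channels), requires_grad=True)
        self.conv = nn.Conv2d(1, 1, kernel, rng)
        self.last_frequency: np.ndarray | None = None
        self.last_spatial: np.ndarray | None = None

    def frequency_weights(self, x: nn.Tensor) -> nn.Tensor:
        pooled = x.mean(axis=(2, 3))                      # (B, C)
        w = (self.fc2(self.fc1(pooled).relu()) + self.bias).sigmoid()
        self.last_frequency = w.data.copy()
        return w

    def spatial_weights(self, x: nn.Tensor) -> nn.Tensor:
        mx = x.max(axis=1, keepdims=True)                  # (B, 1, H, W)
        w = self.conv(mx).relu().sigmoid()
        self.last_spatial = w.data.copy()
        return w

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        fw = self.frequency_weights(x)
        b, c = fw.shape
        xp = x * fw.reshape(b, c, 1, 1)
        return xp * self.spatial_weights(xp)


class CSAM(nn.Module):
    """Cross-scale attention module: parallel 1x1 / 3x3 / 5x5 convolutions
    to the branch width and a 3x3 max pool keeping the stem width, each
    with batch norm + ReLU, concatenated on the channel axis, then gated
    by FSAM (when enabled)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        s, b = cfg.stem_width, cfg.branch_width
        self.convs = [nn.Conv2d(s, b, k, rng) for k in (1, 3, 5)]
        self.bns = [nn.BatchNorm2d(b) for _ in range(3)]
        self.pool = nn.MaxPool2dSame(3)
        self.pool_bn = nn.BatchNorm2d(s)
        self.attention = (
            FSAM(cfg.concat_width, cfg.attention_reduction, cfg.spatial_kernel, rng)
            if cfg.use_fsam
            else None
        )
        self.in_width = s

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.in_width:
            raise ConfigError(f"CSAM expects {self.in_width} input channels, got {x.shape[1]}")
        outs = [bn(conv(x)).relu() for conv, bn in zip(self.convs, self.bns)]
        outs.append(self.pool_bn(self.pool(x)).relu())
        cat = nn.concat(outs, axis=1)
        return self.attention(cat) if self.attention is not None else cat


class SingleScaleConv(nn.Module):
    """Single-kernel replacement for CSAM in the kernel-size ablation."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.conv = nn.Conv2d(cfg.stem_width, cfg.branch_width, cfg.single_scale, rng)
        self.bn = nn.BatchNorm2d(cfg.branch_width)
        self.attention = (
            FSAM(cfg.branch_width, cfg.attention_reduction, cfg.spatial_kernel, rng)
            if cfg.use_fsam
            else None
        )

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        out = self.bn(self.conv(x)).relu()
        return self.attention(out) if self.attention is not None else out


class FTM(nn.Module):
    """Feature transition: batch norm, 1x1 reduction back to the stem
    width, 3x3 same-padding max pool, ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.bn = nn.BatchNorm2d(c_in)
        self.reduce = nn.Conv2d(c_in, c_out, 1, rng)
        self.pool = nn.MaxPool2dSame(3)
        self.c_in = c_in

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.c_in:
            raise ConfigError(f"FTM expects {self.c_in} input channels, got {x.shape[1]}")
        return self.pool(self.reduce(self.bn(x))).relu()


class DCM(nn.Module):
    """Deep classification head: 128 -> 64 -> 32 -> classes with ReLU and
    dropout 0.5 between layers (dropout off at evaluation)."""

    def __init__(self, widths: tuple[int, int, int], n_classes: int, p: float, rng: np.random.Generator):
        w0, w1, w2 = widths
        self.fc1 = nn.Linear(w0, w1, rng)
        self.fc2 = nn.Linear(w1, w2, rng)
        self.fc3 = nn.Linear(w2, n_classes, rng)
        self.drop1 = nn.Dropout(p)
        self.drop2 = nn.Dropout(p)
        self.in_width = w0

    def __call__(self, v: nn.Tensor) -> nn.Tensor:
        if v.shape[1] != self.in_width:
            raise ConfigError(f"classifier expects width {self.in_width}, got {v.shape[1]}")
        h = self.drop1(self.fc1(v).relu())
        h = self.drop2(self.fc2(h).relu())
        return self.fc3(h)


class CATM(nn.Module):
    """The full network; see the module docstring for the data flow."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.stem = nn.Conv2d(cfg.in_planes, cfg.stem_width, 1, rng)
        if cfg.use_csam:
            block_cls = SingleScaleConv if cfg.single_scale is not None else CSAM
            self.blocks = []
            for _ in range(cfg.n_blocks):
                self.blocks.append(block_cls(cfg, rng))
                self.blocks.append(FTM(cfg.concat_width, cfg.stem_width, rng))
        else:
            self.blocks = []
        rows, cols = cfg.grid
        flat = cfg.stem_width * rows * cols
        if cfg.use_bilstm:
            self.proj = nn.Linear(flat, cfg.proj_dim, rng)
            self.lstm = nn.BiLSTM(cfg.proj_dim, cfg.lstm_hidden, rng)
            self.fusion = nn.Linear(2 * cfg.lstm_hidden, cfg.classifier_widths[0], rng)
        else:
            self.proj = nn.Linear(flat, cfg.classifier_widths[0], rng)
            self.lstm = None
            self.fusion = None
        if cfg.use_dcm:
            self.head = DCM(cfg.classifier_widths, cfg.n_classes, cfg.dropout, rng)
        else:
            self.head = nn.Linear(cfg.classifier_widths[0], cfg.n_classes, rng)

    def encode_frames(self, frames: nn.Tensor) -> nn.Tensor:
        """(B*T, planes, H, W) -> (B*T, flat) through stem and blocks."""
        h = self.stem(frames)
        for block in self.blocks:
            h = block(h)
        n = h.shape[0]
        return h.reshape(n, -1)

    def __call__(self, frames: np.ndarray | nn.Tensor) -> nn.Tensor:
        """Forward: frames (B, T, planes, H, W) -> logits (B, n_classes)."""
        x = frames if isinstance(frames, nn.Tensor) else nn.Tensor(frames)
        b, t = x.shape[0], x.shape[1]
        if t != self.cfg.seq_len:
            raise ConfigError(f"expected seq_len {self.cfg.seq_len}, got {t}")
        if x.shape[2] != self.cfg.in_planes:
            raise ConfigError(f"expected {self.cfg.in_planes} planes, got {x.shape[2]}")
        flat_frames = x.reshape(b * t, *x.shape[2:])
        enc = self.proj(self.encode_frames(flat_frames))      # (B*T, L)
        if self.lstm is not None:
            steps = enc.reshape(b, t, -1)
            xs = [steps[:, i, :] for i in range(t)]
            v = self.fusion(self.lstm(xs))
        else:
            v = enc.reshape(b, t, -1).mean(axis=1)            # temporal mean
        return self.head(v)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = rng

    def attention_weights(self) -> list[dict]:
        """Most recent FSAM weights per block (after a forward pass)."""
        out = []
        for m in self.modules():
            if isinstance(m, FSAM):
                out.append({"frequency": m.last_frequency, "spatial": m.last_spatial})
        return out


def build(cfg: ModelConfig | None = None, seed: int = 0) -> CATM:
    """Construct a CATM with reproducible initialization."""
    cfg = cfg if cfg is not None else ModelConfig()
    return CATM(cfg, np.random.default_rng(np.random.SeedSequence((seed, 0xCA7))))


def count_params(model: CATM) -> int:
    """Total trainable scalar count (batch-norm running stats excluded)."""
    return model.n_params()


def _state_arrays(model: CATM) -> dict[str, np.ndarray]:
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i:04d}"] = p.data
    bn_idx = 0
    for m in model.modules():
        if isinstance(m, nn.BatchNorm2d):
            arrays[f"bn_{bn_idx:04d}_mean"] = m.running_mean
            arrays[f"bn_{bn_idx:04d}_var"] = m.running_var
            bn_idx += 1
    return arrays


def save_weights(model: CATM, path) -> None:
    np.savez(path, **_state_arrays(model))


def load_weights(model: CATM, path) -> CATM:
    with np.load(path) as data:
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i:04d}"]
        bn_idx = 0
        for m in model.modules():
            if isinstance(m, nn.BatchNorm2d):
                m.running_mean[...] = data[f"bn_{bn_idx:04d}_mean"]
                m.running_var[...] = data[f"bn_{bn_idx:04d}_var"]
                bn_idx += 1
    return model
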