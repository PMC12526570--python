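"""The dual-branch time/frequency attention classifier.

Architecture overview (all widths configurable):

* **Time branch** — causal 1-D convolution stem and max-pooling, two
  residual convolution blocks (conv-BN-ReLU twice plus a shortcut), a
  cross-scale interactive attention block in which the deep residual
  features act as query and key while a projected global-average-pooled
  reconstruction of the stem features acts as the value (wrapped in
  residual layer normalization), and two stacked BiLSTM layers returning
  the full sequence.
* **Frequency branch** — rows of the spectral self-similarity matrix are
  the token sequence; sinusoidal positional encoding with a learnable
  depthwise-convolution adjustment is added, a Transformer-style encoder
  block (4-head self-attention plus residual layer norm, optional
  feed-forward sublayer) models band-to-band dependencies, a 1x1
  convolution projects channels, and a BiLSTM runs along the band axis.
* **Fusion head** — both branches are projected to a common width, the
  shorter sequence is linearly upsampled and zero-padded to match the
  longer, per-branch channel attention gates the features, cross-attention
  (frequency as query, time as key/value) and self-attention over the
  fused space are merged by a learnable sigmoid gate, and a flatten +
  two fully connected layers + softmax produce the 4-class probabilities.

The default configuration keeps the total trainable parameter count within
ten percent of the 1.46 M budget the architecture targets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention import AttentionConfig
from .exceptions import InvalidParameterError
from .nn import autograd
from .nn.autograd import Tensor, concat, softmax
from .spectral import positional_encoding

__all__ = [
    "TimeBranchConfig", "FreqBranchConfig", "FusionConfig", "HeadConfig",
    "ModelConfig", "DualBranchAttentionNet", "count_parameters",
    "memory_footprint_mb", "default_config", "tiny_config",
    "save_checkpoint", "load_checkpoint", "config_to_dict",
    "config_from_dict",
]

N_CLASSES = 4


@dataclass(frozen=True)
class TimeBranchConfig:
    stem_filters: int = 32
    stem_kernel: int = 7
    pool_size: int = 16
    res_filters: tuple[int, int] = (32, 64)
    res_kernels: tuple[int, int] = (5, 5)
    spatial_dropout: float = 0.2
    csia: AttentionConfig = AttentionConfig(d_model=64, n_heads=4, dropout=0.2)
    bilstm_units: tuple[int, int] = (64, 32)


@dataclass(frozen=True)
class FreqBranchConfig:
    n_bands: int = 32
    transformer: AttentionConfig = AttentionConfig(d_model=32, n_heads=4,
                                                   dropout=0.2)
    ffn_width: int = 64
    ffn: bool = True
    pe_kernel: int = 3
    conv1x1_out: int = 32
    bilstm_units: int = 32


@dataclass(frozen=True)
class FusionConfig:
    common_dim: int = 64
    channel_attn_reduction: int = 4
    cross_attn: AttentionConfig = AttentionConfig(d_model=64, n_heads=4,
                                                  dropout=0.2)
    self_attn: AttentionConfig = AttentionConfig(d_model=64, n_heads=4,
                                                 dropout=0.2)


@dataclass(frozen=True)
class HeadConfig:
    fc1_units: int = 128
    n_classes: int = N_CLASSES


@dataclass(frozen=True)
class ModelConfig:
    window_samples: int = 2500
    time_branch: TimeBranchConfig = TimeBranchConfig()
    freq_branch: FreqBranchConfig = FreqBranchConfig()
    fusion: FusionConfig = FusionConfig()
    head: HeadConfig = HeadConfig()
    dropout: float = 0.2
    # ablation switches
    use_time: bool = True
    use_freq: bool = True
    use_residual: bool = True
    use_csia: bool = True
    use_cross_attention: bool = True

    def validate(self) -> None:
        if self.head.n_classes != N_CLASSES:
            raise InvalidParameterError("final layer width must be 4")
        if not (self.use_time or self.use_freq):
            raise InvalidParameterError("at least one branch must be enabled")
        self.time_branch.csia.validate()
        self.freq_branch.transformer.validate()
        self.fusion.cross_attn.validate()
        self.fusion.self_attn.validate()
        if self.freq_branch.n_bands < 2:
            raise InvalidParameterError("n_bands must be >= 2")


def default_config(window_samples: int = 2500) -> ModelConfig:
    return ModelConfig(window_samples=window_samples)


def tiny_config(window_samples: int = 2500) -> ModelConfig:
    """Reduced-width preset for CPU-scale experiments and tests."""
    return ModelConfig(
        window_samples=window_samples,
        time_branch=TimeBranchConfig(
            stem_filters=8, stem_kernel=7, pool_size=25,
            res_filters=(8, 16), res_kernels=(5, 5), spatial_dropout=0.1,
            csia=AttentionConfig(d_model=16, n_heads=2, dropout=0.1),
            bilstm_units=(16, 8)),
        freq_branch=FreqBranchConfig(
            n_bands=16,
            transformer=AttentionConfig(d_model=16, n_heads=2, dropout=0.1),
            ffn_width=32, conv1x1_out=16, bilstm_units=8),
        fusion=FusionConfig(
            common_dim=16, channel_attn_reduction=4,
            cross_attn=AttentionConfig(d_model=16, n_heads=2, dropout=0.1),
            self_attn=AttentionConfig(d_model=16, n_heads=2, dropout=0.1)),
        head=HeadConfig(fc1_units=32),
        dropout=0.1)


class ResidualBlock(nn.Module):
    """Two conv-BN stages with a shortcut: y = ReLU(BN(conv2(ReLU(BN(
    conv1(x))))) + shortcut(x)); the shortcut is the identity when channel
    counts match, a 1x1 convolution otherwise."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, use_residual: bool = True):
        super().__init__()
        self.conv1 = nn.Conv1D(c_in, c_out, kernel, rng)
        self.bn1 = nn.BatchNorm(c_out)
        self.conv2 = nn.Conv1D(c_out, c_out, kernel, rng)
        self.bn2 = nn.BatchNorm(c_out)
        self.use_residual = use_residual
        self.shortcut = (None if c_in == c_out or not use_residual
                         else nn.Conv1D(c_in, c_out, 1, rng))

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        if self.use_residual:
            sc = x if self.shortcut is None else self.shortcut(x)
            y = y + sc
        return y.relu()


class TimeBranch(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        tb = cfg.time_branch
        self.cfg = tb
        self.use_csia = cfg.use_csia
        self.stem = nn.Conv1D(1, tb.stem_filters, tb.stem_kernel, rng,
                              padding="causal")
        self.pool = nn.MaxPool1D(tb.pool_size)
        self.res1 = ResidualBlock(tb.stem_filters, tb.res_filters[0],
                                  tb.res_kernels[0], rng, cfg.use_residual)
        self.res2 = ResidualBlock(tb.res_filters[0], tb.res_filters[1],
                                  tb.res_kernels[1], rng, cfg.use_residual)
        self.sdrop1 = nn.SpatialDropout1D(tb.spatial_dropout, rng)
        self.sdrop2 = nn.SpatialDropout1D(tb.spatial_dropout, rng)
        d = tb.csia.d_model
        self.res_proj = nn.Dense(tb.res_filters[1], d, rng)
        if self.use_csia:
            self.value_proj = nn.Dense(tb.stem_filters, d, rng)
            self.mha = nn.MultiHeadAttention(d, tb.csia.n_heads, rng,
                                             dropout=tb.csia.dropout)
            self.resnorm = nn.ResidualLayerNorm(d)
            self.attn_drop = nn.Dropout(tb.csia.dropout, rng)
        self.bilstm1 = nn.BiLSTM(d, tb.bilstm_units[0], rng)
        self.drop = nn.Dropout(tb.csia.dropout, rng)
        self.bilstm2 = nn.BiLSTM(2 * tb.bilstm_units[0], tb.bilstm_units[1],
                                 rng)

    def stem_features(self, x: Tensor) -> Tensor:
        """Pre-pool causal stem output (causality is testable here)."""
        return self.stem(x).relu()

    def forward(self, x: Tensor) -> Tensor:
        s = self.pool(self.stem_features(x))
        f = self.sdrop1(self.res1(s))
        f = self.sdrop2(self.res2(f))
        qk = self.res_proj(f)
        if self.use_csia:
            b, t, d = qk.shape
            pooled = s.mean(axis=1)                        # GAP over time
            v = self.value_proj(pooled).reshape(b, 1, d).broadcast_to(
                (b, t, d))
            att = self.attn_drop(self.mha(qk, qk, v))
            y = self.resnorm(qk, att)
        else:
            y = qk
        h = self.drop(self.bilstm1(y))
        return self.bilstm2(h)

    @property
    def out_channels(self) -> int:
        return 2 * self.cfg.bilstm_units[1]


class FreqBranch(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        fb = cfg.freq_branch
        self.cfg = fb
        d = fb.transformer.d_model
        self.token_proj = (None if fb.n_bands == d
                           else nn.Dense(fb.n_bands, d, rng))
        pe_dim = fb.n_bands if self.token_proj is not None else d
        self.pe = positional_encoding(fb.n_bands, pe_dim)
        self.pe_conv = nn.DepthwiseConv1D(pe_dim, fb.pe_kernel, rng,
                                          zero_init=True)
        self.mha = nn.MultiHeadAttention(d, fb.transformer.n_heads, rng,
                                         dropout=fb.transformer.dropout)
        self.norm1 = nn.ResidualLayerNorm(d)
        self.drop1 = nn.Dropout(fb.transformer.dropout, rng)
        if fb.ffn:
            self.ffn1 = nn.Dense(d, fb.ffn_width, rng)
            self.ffn2 = nn.Dense(fb.ffn_width, d, rng)
            self.norm2 = nn.ResidualLayerNorm(d)
            self.drop2 = nn.Dropout(fb.transformer.dropout, rng)
        self.conv1x1 = nn.Dense(d, fb.conv1x1_out, rng)
        self.bilstm = nn.BiLSTM(fb.conv1x1_out, fb.bilstm_units, rng)

    def adjusted_pe(self) -> Tensor:
        """Sinusoidal positional encoding plus the learnable depthwise
        convolutional adjustment (residual; identity at zero init)."""
        pe = Tensor(self.pe[None, :, :])
        return pe + self.pe_conv(pe)

    def forward(self, ssm: Tensor) -> Tensor:
        x = ssm + self.adjusted_pe()
        if self.token_proj is not None:
            x = self.token_proj(x)
        att = self.drop1(self.mha(x, x, x))
        x = self.norm1(x, att)
        if self.cfg.ffn:
            f = self.ffn2(self.ffn1(x).relu())
            x = self.norm2(x, self.drop2(f))
        x = self.conv1x1(x)
        return self.bilstm(x)

    @property
    def out_channels(self) -> int:
        return 2 * self.cfg.bilstm_units


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation resize matrix M with y = M x (length n_in ->
    n_out)."""
    m = np.zeros((n_out, n_in))
    pos = np.linspace(0, n_in - 1, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m


class FusionHead(nn.Module):
    def __init__(self, cfg: ModelConfig, t_time: int, c_time: int,
                 t_freq: int, c_freq: int, rng: np.random.Generator):
        super().__init__()
        fu = cfg.fusion
        self.cfg = cfg
        c = fu.common_dim
        self.t_out = max(t_time, t_freq) if (cfg.use_time and cfg.use_freq) \
            else (t_time if cfg.use_time else t_freq)
        if cfg.use_time:
            self.proj_t = nn.Dense(c_time, c, rng)
            self.ca_t = nn.ChannelAttention(c, fu.channel_attn_reduction, rng)
        if cfg.use_freq:
            self.proj_f = nn.Dense(c_freq, c, rng)
            self.ca_f = nn.ChannelAttention(c, fu.channel_attn_reduction, rng)
        both = cfg.use_time and cfg.use_freq
        if both:
            # upsample-then-pad alignment of the shorter sequence
            short = min(t_time, t_freq)
            factor = max(1, self.t_out // short)
            self.align_m = _interp_matrix(short, short * factor)
            self.align_pad = self.t_out - short * factor
            if cfg.use_cross_attention:
                self.cross = nn.MultiHeadAttention(
                    c, fu.cross_attn.n_heads, rng,
                    dropout=fu.cross_attn.dropout)
                self.cross_norm = nn.ResidualLayerNorm(c)
                self.cross_drop = nn.Dropout(fu.cross_attn.dropout, rng)
            self.fuse_proj = nn.Dense(2 * c, c, rng)
            self.selfattn = nn.MultiHeadAttention(
                c, fu.self_attn.n_heads, rng, dropout=fu.self_attn.dropout)
            self.self_norm = nn.ResidualLayerNorm(c)
            self.self_drop = nn.Dropout(fu.self_attn.dropout, rng)
            if cfg.use_cross_attention:
                self.gate = nn.GatedFusion(c, rng)
        self.head_drop = nn.Dropout(cfg.dropout, rng)
        self.fc1 = nn.Dense(self.t_out * c, cfg.head.fc1_units, rng)
        self.fc1_drop = nn.Dropout(cfg.dropout, rng)
        self.fc2 = nn.Dense(cfg.head.fc1_units, cfg.head.n_classes, rng)

    def _align(self, x: Tensor) -> Tensor:
        """Linear 1-D upsampling of the shorter sequence followed by
        zero-padding to the exact common length."""
        y = Tensor(self.align_m) @ x
        if self.align_pad > 0:
            b, t, c = y.shape
            y = concat([y, Tensor(np.zeros((b, self.align_pad, c)))], axis=1)
        return y

    def forward(self, ht: Tensor | None, hf: Tensor | None) -> Tensor:
        cfg = self.cfg
        if cfg.use_time and cfg.use_freq:
            pt = self.proj_t(ht)
            pf = self.proj_f(hf)
            if pf.shape[1] < pt.shape[1]:
                pf = self._align(pf)
            elif pt.shape[1] < pf.shape[1]:
                pt = self._align(pt)
            at = self.ca_t(pt)
            af = self.ca_f(pf)
            fused = self.fuse_proj(concat([at, af], axis=-1))
            sa = self.self_norm(fused, self.self_drop(
                self.selfattn(fused, fused, fused)))
            if cfg.use_cross_attention:
                ca = self.cross_norm(af, self.cross_drop(
                    self.cross(af, at, at)))
                g = self.gate(ca, sa)
            else:
                g = sa
        else:
            x = self.proj_t(ht) if cfg.use_time else self.proj_f(hf)
            g = (self.ca_t if cfg.use_time else self.ca_f)(x)
        g = self.head_drop(g)
        b = g.shape[0]
        flat = g.reshape(b, g.shape[1] * g.shape[2])
        h1 = self.fc1_drop(self.fc1(flat).relu())
        return softmax(self.fc2(h1), axis=-1)


class DualBranchAttentionNet(nn.Module):
    """Full classifier: time branch + frequency branch + fusion head.

    ``forward`` takes a [batch, window_samples] (or [batch, T, 1]) signal
    matrix and a [batch, B, B] stack of self-similarity matrices and
    returns [batch, 4] class probabilities summing to one.
    """

    def __init__(self, cfg: ModelConfig = None, seed: int = 0):
        super().__init__()
        cfg = cfg if cfg is not None else default_config()
        cfg.validate()
        self.config = cfg
        rng = np.random.default_rng(seed)
        t_time = cfg.window_samples // cfg.time_branch.pool_size
        self.time_branch = TimeBranch(cfg, rng) if cfg.use_time else None
        self.freq_branch = FreqBranch(cfg, rng) if cfg.use_freq else None
        c_time = self.time_branch.out_channels if cfg.use_time else 0
        c_freq = self.freq_branch.out_channels if cfg.use_freq else 0
        self.fusion = FusionHead(cfg, t_time, c_time,
                                 cfg.freq_branch.n_bands, c_freq, rng)

    def forward(self, x_time, x_ssm) -> Tensor:
        cfg = self.config
        ht = hf = None
        if cfg.use_time:
            xt = x_time if isinstance(x_time, Tensor) else Tensor(x_time)
            if xt.ndim == 2:
                xt = xt.reshape(xt.shape[0], xt.shape[1], 1)
            ht = self.time_branch(xt)
        if cfg.use_freq:
            xf = x_ssm if isinstance(x_ssm, Tensor) else Tensor(x_ssm)
            hf = self.freq_branch(xf)
        probs = self.fusion(ht, hf)
        if not np.all(np.isfinite(probs.data)):
            raise FloatingPointError(
                "non-finite class probabilities; inputs or weights diverged")
        return probs

    def predict_proba(self, x_time: np.ndarray, x_ssm: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Inference-mode probabilities (dropout off, no graph built)."""
        was_training = self.training
        self.eval()
        try:
            out = []
            with autograd.no_grad():
                for lo in range(0, len(x_time), batch_size):
                    out.append(self.forward(
                        x_time[lo: lo + batch_size],
                        x_ssm[lo: lo + batch_size]).data)
            return np.concatenate(out, axis=0)
        finally:
            if was_training:
                self.train()

    def predict(self, x_time: np.ndarray, x_ssm: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x_time, x_ssm, batch_size).argmax(axis=1)


def count_parameters(cfg: ModelConfig | DualBranchAttentionNet) -> int:
    """Exact count of trainable scalars for a configuration (or model)."""
    model = (cfg if isinstance(cfg, DualBranchAttentionNet)
             else DualBranchAttentionNet(cfg, seed=0))
    return model.n_parameters()


def memory_footprint_mb(n_params: int, bytes_per_param: int = 4) -> float:
    """Model size in MB (MiB convention) at the given precision."""
    return n_params * bytes_per_param / 2 ** 20


# ---------------------------------------------------------------------------
# configuration (de)serialization and self-describing checkpoints

_CONFIG_TYPES = {
    "time_branch": TimeBranchConfig,
    "freq_branch": FreqBranchConfig,
    "fusion": FusionConfig,
    "head": HeadConfig,
    "csia": AttentionConfig,
    "transformer": AttentionConfig,
    "cross_attn": AttentionConfig,
    "self_attn": AttentionConfig,
}


def config_to_dict(cfg) -> dict:
    d = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        d[f.name] = config_to_dict(v) if dataclasses.is_dataclass(v) else (
            list(v) if isinstance(v, tuple) else v)
    return d


def config_from_dict(data: dict, cls=ModelConfig):
    """Rebuild a (nested) config dataclass, rejecting unknown keys."""
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise InvalidParameterError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, dict) and key in _CONFIG_TYPES:
            kwargs[key] = config_from_dict(value, _CONFIG_TYPES[key])
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def save_checkpoint(model: DualBranchAttentionNet, path: str | Path) -> None:
    """Single-file archive of named weight arrays with the full model
    configuration serialized alongside (self-describing)."""
    path = Path(path)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config_to_dict(model.config)).encode(), dtype=np.uint8)
    np.savez_compressed(path, **state)


def load_checkpoint(path: str | Path) -> DualBranchAttentionNet:
    path = Path(path)
    if not path.exists() and path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path, allow_pickle=False) as z:
        cfg_json = bytes(z["__config__"]).decode()
        cfg = config_from_dict(json.loads(cfg_json))
        model = DualBranchAttentionNet(cfg, seed=0)
        state = {k: z[k] for k in z.files if k != "__config__"}
    model.load_state_dict(state)
    return model
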