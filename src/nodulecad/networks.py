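"""MSFE backbone, MSFD-Net detector, and CS-Net candidate scorer.

MSFE is a 3D encoder-decoder: five encoding layers (a plain
conv-BN-ReLU stem, then four max-pool + stacked squeeze-and-excitation
residual blocks), and two decoding layers (transposed convolution,
U-Net-style skip concatenation, two residual-SE blocks each).  The
decoder emits two feature maps: S3 at stride 8 (coarse, for large
anchors) and S2 at stride 4 (fine, for small anchors).

MSFD-Net = MSFE + a candidate prediction head: per scale, one
classification predictor (1 logit per anchor) and one regression
predictor (4 offsets per anchor), each conv3-BN-ReLU-conv1.  Outputs
are flattened in the anchor-grid order (scale-major, grid-point,
diameter).

CS-Net = a lightweight MSFE on 32^3 candidate patches + per-scale 1^3
convolutions to 128 channels, global average pooling, concatenation to
a 256-vector, and a small fully connected classifier emitting one
score.

Default widths are calibrated so that the detector holds ~3.30 M and
the scorer ~1.52 M trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .anchors import SCALES, build_anchor_grid
from .nn import Tensor

__all__ = [
    "MSFEConfig",
    "DetectorConfig",
    "ScorerConfig",
    "MSFE",
    "MSFDNet",
    "CSNet",
    "default_detector_config",
    "default_scorer_config",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class MSFEConfig:
    in_channels: int = 1
    encoder_widths: tuple[int, ...] = (16, 32, 56, 64, 64)
    blocks_per_layer: tuple[int, ...] = (2, 2, 3, 3)
    decoder_width: int = 64
    se_reduction: int = 4
    dropout_p: float = 0.2
    #: statistics used by batch-norm outside training: "input" (per-sample
    #: instance statistics; robust when training batches are tiny) or
    #: "running" (tracked averages; appropriate with larger batches)
    bn_eval_stats: str = "input"

    def __post_init__(self):
        if len(self.encoder_widths) != 5:
            raise ValueError("encoder_widths must have 5 entries")
        if len(self.blocks_per_layer) != 4:
            raise ValueError("blocks_per_layer must have 4 entries (layers 2-5)")
        if any(w <= 0 for w in self.encoder_widths) or self.decoder_width <= 0:
            raise ValueError("widths must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0,1)")

    def scaled(self, factor: float) -> "MSFEConfig":
        """Width-scaled copy (e.g. 0.5 for the reduced desk-scale model)."""
        return replace(
            self,
            encoder_widths=tuple(max(4, int(round(w * factor)))
                                 for w in self.encoder_widths),
            decoder_width=max(4, int(round(self.decoder_width * factor))),
        )


@dataclass(frozen=True)
class DetectorConfig:
    msfe: MSFEConfig = field(default_factory=MSFEConfig)
    head_width: int = 64

    def scaled(self, factor: float) -> "DetectorConfig":
        return replace(self, msfe=self.msfe.scaled(factor),
                       head_width=max(4, int(round(self.head_width * factor))))


@dataclass(frozen=True)
class ScorerConfig:
    msfe: MSFEConfig = field(
        default_factory=lambda: MSFEConfig(
            encoder_widths=(16, 24, 40, 64, 78),
            blocks_per_layer=(1, 1, 2, 2),
            decoder_width=32,
            bn_eval_stats="running",
        )
    )
    agg_channels: int = 128
    hidden: int = 64

    def scaled(self, factor: float) -> "ScorerConfig":
        return replace(self, msfe=self.msfe.scaled(factor),
                       agg_channels=max(8, int(round(self.agg_channels * factor))),
                       hidden=max(8, int(round(self.hidden * factor))))


def default_detector_config() -> DetectorConfig:
    return DetectorConfig()


def default_scorer_config() -> ScorerConfig:
    return ScorerConfig()


class ConvBlock(nn.Module):
    """3^3 convolution + batch norm (activation applied by the caller)."""

    def __init__(self, cin, cout, rng, bn_eval_stats="input"):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, 3, rng, bias=False)
        self.bn = nn.BatchNorm3d(cout, eval_stats=bn_eval_stats)

    def __call__(self, x):
        return self.bn(self.conv(x))


class ResSEBlock(nn.Module):
    """[conv-BN-ReLU, conv-BN] + squeeze-excitation gate + residual add.

    The shortcut is a 1^3 convolution when the channel count changes.
    Setting ``se_enabled=False`` fixes the gate at 1 and recovers a
    plain residual block (ablation hook).
    """

    def __init__(self, cin, cout, rng, se_reduction=4, se_enabled=True,
                 bn_eval_stats="input"):
        super().__init__()
        self.conv1 = nn.Conv3d(cin, cout, 3, rng, bias=False)
        self.bn1 = nn.BatchNorm3d(cout, eval_stats=bn_eval_stats)
        self.conv2 = nn.Conv3d(cout, cout, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm3d(cout, eval_stats=bn_eval_stats)
        hidden = max(cout // se_reduction, 4)
        self.fc1 = nn.Linear(cout, hidden, rng)
        self.fc2 = nn.Linear(hidden, cout, rng)
        self.shortcut = nn.Conv3d(cin, cout, 1, rng, bias=True) if cin != cout else None
        self.se_enabled = se_enabled

    def se_gate(self, h: Tensor) -> Tensor:
        pooled = h.mean(axis=(2, 3, 4))  # (N, C)
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(pooled))))

    def __call__(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        if self.se_enabled:
            gate = self.se_gate(h)
            n, c = gate.shape
            h = h * gate.reshape(n, c, 1, 1, 1)
        identity = self.shortcut(x) if self.shortcut is not None else x
        return nn.relu(h + identity)


class _Stack(nn.Module):
    def __init__(self, blocks):
        super().__init__()
        self.blocks = nn.ModuleList(blocks)

    def __call__(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class MSFE(nn.Module):
    """Multi-scale feature extractor; returns (S2, S3) feature maps."""

    def __init__(self, config: MSFEConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        w = config.encoder_widths
        r = config.se_reduction
        es = config.bn_eval_stats
        self.stem = ConvBlock(config.in_channels, w[0], rng, bn_eval_stats=es)
        self.pool = nn.MaxPool3d()
        enc = []
        for layer, n_blocks in enumerate(config.blocks_per_layer):
            cin, cout = w[layer], w[layer + 1]
            blocks = [ResSEBlock(cin, cout, rng, r, bn_eval_stats=es)]
            blocks += [ResSEBlock(cout, cout, rng, r, bn_eval_stats=es)
                       for _ in range(n_blocks - 1)]
            enc.append(_Stack(blocks))
        self.enc = nn.ModuleList(enc)
        dw = config.decoder_width
        self.up1 = nn.ConvTranspose3d2x(w[4], dw, rng)
        self.dec1 = _Stack([ResSEBlock(dw + w[3], dw, rng, r, bn_eval_stats=es),
                            ResSEBlock(dw, dw, rng, r, bn_eval_stats=es)])
        self.up2 = nn.ConvTranspose3d2x(dw, dw, rng)
        self.dec2 = _Stack([ResSEBlock(dw + w[2], dw, rng, r, bn_eval_stats=es),
                            ResSEBlock(dw, dw, rng, r, bn_eval_stats=es)])
        self.drop = nn.Dropout(config.dropout_p, rng)

    def __call__(self, x) -> tuple[Tensor, Tensor]:
        x = nn.as_tensor(x)
        if any(s % 16 for s in x.shape[2:]):
            raise ValueError(f"input spatial shape {x.shape[2:]} must be divisible by 16")
        e1 = nn.relu(self.stem(x))         # stride 1
        e2 = self.enc[0](self.pool(e1))    # stride 2
        e3 = self.enc[1](self.pool(e2))    # stride 4
        e4 = self.enc[2](self.pool(e3))    # stride 8
        e5 = self.enc[3](self.pool(e4))    # stride 16
        s3 = self.dec1(nn.concat([self.up1(e5), e4], axis=1))
        s3 = self.drop(s3)
        s2 = self.dec2(nn.concat([self.up2(s3), e3], axis=1))
        s2 = self.drop(s2)
        return s2, s3


class _Predictor(nn.Module):
    """conv3-BN-ReLU-conv1 head emitting ``out_channels`` per voxel.

    Classification heads start with a negative bias so the initial
    foreground probability is low (~2%); this skips the early phase in
    which the focal loss merely drives all outputs to the background
    prior and lets training separate classes from the first steps.
    """

    def __init__(self, cin, width, out_channels, rng, prior_bias: float = 0.0):
        super().__init__()
        self.conv = nn.Conv3d(cin, width, 3, rng, bias=False)
        self.bn = nn.BatchNorm3d(width)
        self.head = nn.Conv3d(width, out_channels, 1, rng, bias=True)
        if prior_bias:
            self.head.bias.data[:] = prior_bias

    def __call__(self, x):
        return self.head(nn.relu(self.bn(self.conv(x))))


def _flatten_head(t: Tensor, n_anchors: int, channels: int) -> Tensor:
    """(N, n_anchors*channels, D, H, W) -> (N, D*H*W*n_anchors, channels)."""
    n = t.shape[0]
    d, h, w = t.shape[2:]
    t = t.reshape(n, n_anchors, channels, d, h, w)
    t = t.transpose((0, 3, 4, 5, 1, 2))
    return t.reshape(n, d * h * w * n_anchors, channels)


class MSFDNet(nn.Module):
    """Detector: MSFE + two-scale candidate prediction network."""

    def __init__(self, config: DetectorConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or default_detector_config()
        rng = np.random.default_rng(seed)
        self.msfe = MSFE(self.config.msfe, rng)
        dw = self.config.msfe.decoder_width
        hw = self.config.head_width
        self.n_anchors = {name: len(diams) for name, (_, diams) in SCALES.items()}
        self.cls_s2 = _Predictor(dw, hw, self.n_anchors["S2"], rng, prior_bias=-4.0)
        self.reg_s2 = _Predictor(dw, hw, self.n_anchors["S2"] * 4, rng)
        self.cls_s3 = _Predictor(dw, hw, self.n_anchors["S3"], rng, prior_bias=-4.0)
        self.reg_s3 = _Predictor(dw, hw, self.n_anchors["S3"] * 4, rng)

    def __call__(self, patch) -> tuple[Tensor, Tensor]:
        """Returns (cls logits (N, A, 1), reg offsets (N, A, 4))."""
        s2, s3 = self.msfe(patch)
        cls = nn.concat(
            [_flatten_head(self.cls_s2(s2), self.n_anchors["S2"], 1),
             _flatten_head(self.cls_s3(s3), self.n_anchors["S3"], 1)], axis=1)
        reg = nn.concat(
            [_flatten_head(self.reg_s2(s2), self.n_anchors["S2"], 4),
             _flatten_head(self.reg_s3(s3), self.n_anchors["S3"], 4)], axis=1)
        return cls, reg


class CSNet(nn.Module):
    """Candidate scorer on 1x32x32x32 gray patches."""

    PATCH_SHAPE = (32, 32, 32)

    def __init__(self, config: ScorerConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or default_scorer_config()
        rng = np.random.default_rng(seed)
        self.msfe = MSFE(self.config.msfe, rng)
        dw = self.config.msfe.decoder_width
        ac = self.config.agg_channels
        self.agg_s2 = nn.Conv3d(dw, ac, 1, rng, bias=True)
        self.agg_s3 = nn.Conv3d(dw, ac, 1, rng, bias=True)
        self.fc1 = nn.Linear(2 * ac, self.config.hidden, rng)
        self.fc2 = nn.Linear(self.config.hidden, 1, rng)

    def features(self, patch) -> Tensor:
        """The aggregated 256-length candidate feature vector."""
        patch = nn.as_tensor(patch)
        if tuple(patch.shape[2:]) != self.PATCH_SHAPE:
            raise ValueError(
                f"CS-Net expects Nx1x32x32x32 patches, got {tuple(patch.shape)}")
        s2, s3 = self.msfe(patch)
        f2 = self.agg_s2(s2).mean(axis=(2, 3, 4))
        f3 = self.agg_s3(s3).mean(axis=(2, 3, 4))
        return nn.concat([f2, f3], axis=1)

    def logits(self, patch) -> Tensor:
        return self.fc2(nn.relu(self.fc1(self.features(patch))))

    def __call__(self, patch) -> Tensor:
        """Candidate score in (0, 1), shape (N, 1)."""
        return nn.sigmoid(self.logits(patch))


def count_parameters(model_or_config) -> int:
    """Total trainable scalar parameters of a model or config."""
    if isinstance(model_or_config, nn.Module):
        return model_or_config.n_parameters()
    if isinstance(model_or_config, DetectorConfig):
        return MSFDNet(model_or_config).n_parameters()
    if isinstance(model_or_config, ScorerConfig):
        return CSNet(model_or_config).n_parameters()
    raise TypeError(f"cannot count parameters of {type(model_or_config)!r}")


# -- checkpointing -----------------------------------------------------

def _config_to_dict(config) -> dict:
    d = asdict(config)
    d["__class__"] = type(config).__name__
    return d


def _config_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("__class__")
    def _tup(m):
        return {k: tuple(v) if isinstance(v, list) else v for k, v in m.items()}
    if kind == "DetectorConfig":
        return DetectorConfig(msfe=MSFEConfig(**_tup(d.pop("msfe"))), **d)
    if kind == "ScorerConfig":
        return ScorerConfig(msfe=MSFEConfig(**_tup(d.pop("msfe"))), **d)
    raise ValueError(f"unknown config class {kind}")


def save_checkpoint(model: nn.Module, path: str | Path) -> None:
    """Save parameters, batch-norm buffers and the embedded config."""
    path = Path(path)
    arrays = {"param:" + k: v.data for k, v in model.named_parameters()}
    arrays.update({"buffer:" + k: v for k, v in model.buffers()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(_config_to_dict(model.config)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> nn.Module:
    with np.load(Path(path), allow_pickle=False) as data:
        config = _config_from_dict(
            json.loads(bytes(data["config_json"].tobytes()).decode())
        )
        model = MSFDNet(config) if isinstance(config, DetectorConfig) else CSNet(config)
        params = dict(model.named_parameters())
        for key in data.files:
            if key.startswith("param:"):
                params[key[6:]].data = data[key].astype(np.float32)
        buffers = dict(model.buffers())
        for key in data.files:
            if key.startswith("buffer:"):
                buffers[key[7:]][...] = data[key]
    return model
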