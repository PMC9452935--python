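"""Residual-encoder / SE-atrous-decoder segmentation network.

The architecture is a U-Net-style encoder--decoder for single white blood
cell (leukocyte) segmentation:

* **Encoder** — a ResNet50-style backbone reduced to its convolutional
  trunk: a 7x7 stride-2 convolution + 3x3 max pooling as the first
  downsampling unit, then four stages of bottleneck residual blocks
  (3, 4, 6 and 3 blocks) producing 256/512/1024/2048-channel feature maps
  at 1/4 .. 1/32 of the input resolution.
* **Decoder** — four upsampling units, each: bilinear 2x upsampling,
  concatenation with the matching encoder skip, a 1x1 channel-mixing
  convolution, a 3x3 convolution (BN + ReLU), a 3x3 atrous convolution
  (BN + ReLU) that widens the receptive field without extra parameters,
  and a squeeze-and-excitation (SE) channel-attention block.  A final
  bilinear 2x upsampling, 1x1 convolution and sigmoid produce a
  full-resolution foreground-probability map in [0, 1].

All convolutions are padded so spatial size is preserved (stride aside),
and all upsampling is bilinear interpolation — transposed convolutions are
avoided because of their checkerboard artifacts.

``width_multiplier`` scales every channel count uniformly, giving a
desk-scale variant of the same topology for fast CPU experiments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .nn import (BatchNorm2d, Conv2d, Linear, MaxPool2d, Module, ModuleList,
                 UpsampleBilinear2x, init_parameters)

# base (width_multiplier = 1) channel plan of the backbone
_STAGE_MID = (64, 128, 256, 512)
_STAGE_OUT = (256, 512, 1024, 2048)
_STEM_OUT = 64


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """All architectural knobs of the segmentation network.

    Attributes
    ----------
    in_channels : input image channels (RGB microscopy -> 3).
    input_side : square input size in pixels; must be divisible by 32 so
        the five halvings land on integer sizes.
    block_counts : residual blocks per encoder stage (backbone default
        3, 4, 6, 3).
    se_reduction_R : reduction ratio R of the SE bottleneck (default 6).
    dilation_rate_d : dilation rate d of the decoder's atrous convolutions;
        an int applies to all four units, or a 4-tuple sets them per unit.
    width_multiplier : uniform channel scaling; < 1 only for desk-scale runs.
    sigmoid_output : the output head always ends in a sigmoid.
    pretrained_source : optional path to an encoder weight archive.
    """

    in_channels: int = 3
    input_side: int = 256
    block_counts: tuple = (3, 4, 6, 3)
    se_reduction_R: int = 6
    dilation_rate_d: int | tuple = 2
    width_multiplier: float = 1.0
    sigmoid_output: bool = True
    pretrained_source: str | None = None

    def __post_init__(self):
        self.block_counts = tuple(int(b) for b in self.block_counts)
        if self.input_side % 32 != 0:
            raise ConfigurationError(
                f"input_side must be divisible by 32, got {self.input_side}")
        if len(self.block_counts) != 4 or any(b < 1 for b in self.block_counts):
            raise ConfigurationError(
                "block_counts must be 4 entries, each >= 1")
        if self.se_reduction_R < 1:
            raise ConfigurationError("se_reduction_R must be >= 1")
        if self.width_multiplier <= 0:
            raise ConfigurationError("width_multiplier must be positive")
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        for d in self.dilations():
            if d < 1:
                raise ConfigurationError("dilation rate must be >= 1")
        if not self.sigmoid_output:
            raise ConfigurationError("sigmoid_output is always true")

    def dilations(self) -> tuple:
        d = self.dilation_rate_d
        if isinstance(d, (tuple, list)):
            if len(d) != 4:
                raise ConfigurationError("per-unit dilation needs 4 entries")
            return tuple(int(x) for x in d)
        return (int(d),) * 4

    def scaled(self, channels: int) -> int:
        return max(1, round(channels * self.width_multiplier))

    # -- (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_counts"] = list(self.block_counts)
        if isinstance(d["dilation_rate_d"], tuple):
            d["dilation_rate_d"] = list(d["dilation_rate_d"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "NetworkConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------
# receptive field of an atrous convolution
# ---------------------------------------------------------------------

def receptive_field(k: int, d: int) -> int:
    """Side of the receptive field of a kxk convolution with dilation d,
    computed as v = (k+1)(d-1) + k.

    This is the rule this implementation standardizes on for reporting
    atrous receptive fields (a 3x3 kernel at d=2 covers a 7x7 field).
    The conventional effective-kernel size is available as
    :func:`effective_kernel_size`.
    """
    k, d = _check_kd(k, d)
    return (k + 1) * (d - 1) + k


def effective_kernel_size(k: int, d: int) -> int:
    """Conventional dilated-kernel extent k + (k-1)(d-1)."""
    k, d = _check_kd(k, d)
    return k + (k - 1) * (d - 1)


def _check_kd(k, d):
    k, d = int(k), int(d)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {k}")
    if d < 1:
        raise ValueError(f"dilation rate must be a positive integer, got {d}")
    return k, d


# ---------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------

class Bottleneck(Module):
    """Residual bottleneck: 1x1 -> BN -> ReLU -> 3x3 -> BN -> ReLU -> 1x1
    -> BN on the residual path, identity (or projection 1x1 conv + BN when
    channels/resolution change) on the shortcut, joined by addition + ReLU.
    Downsampling stride sits on the 3x3 convolution."""

    def __init__(self, in_channels: int, mid_channels: int, out_channels: int,
                 stride: int = 1):
        super().__init__()
        if min(in_channels, mid_channels, out_channels) < 1:
            raise ValueError("channel counts must be >= 1")
        self.conv1 = Conv2d(in_channels, mid_channels, 1, bias=False)
        self.bn1 = BatchNorm2d(mid_channels)
        self.conv2 = Conv2d(mid_channels, mid_channels, 3, stride=stride,
                            padding=1, bias=False)
        self.bn2 = BatchNorm2d(mid_channels)
        self.conv3 = Conv2d(mid_channels, out_channels, 1, bias=False)
        self.bn3 = BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.proj_conv = Conv2d(in_channels, out_channels, 1,
                                    stride=stride, padding=0, bias=False)
            self.proj_bn = BatchNorm2d(out_channels)
        else:
            self.proj_conv = None
            self.proj_bn = None

    def forward(self, x):
        r = nn.relu(self.bn1(self.conv1(x)))
        r = nn.relu(self.bn2(self.conv2(r)))
        r = self.bn3(self.conv3(r))
        ident = self.proj_bn(self.proj_conv(x)) if self.proj_conv else x
        return nn.relu(r + ident)


def build_residual_block(in_channels: int, mid_channels: int,
                         out_channels: int, downsample: bool = False,
                         seed: int = 0) -> Bottleneck:
    """Standalone bottleneck block with deterministic He initialization."""
    block = Bottleneck(in_channels, mid_channels, out_channels,
                       stride=2 if downsample else 1)
    return init_parameters(block, seed)


class SqueezeExcite(Module):
    """SE channel attention: global average pool (squeeze), an FC
    bottleneck C -> floor(C/R) (clamped to >= 1) with ReLU, an FC back to C
    with sigmoid (excitation), then channel-wise rescaling."""

    def __init__(self, channels: int, reduction: int = 6):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction ratio must be >= 1")
        self.channels = channels
        self.reduction = reduction
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden)
        self.fc2 = Linear(hidden, channels)

    def channel_weights(self, x):
        s = nn.global_avg_pool(x)
        s = nn.relu(self.fc1(s))
        return nn.sigmoid(self.fc2(s))

    def forward(self, x):
        w = self.channel_weights(x)
        n, c = w.shape
        return x * nn.reshape(w, (n, c, 1, 1))


def se_recalibrate(x, R: int = 6, seed: int = 0):
    """Apply a freshly (He-)initialized SE block of reduction R to ``x``."""
    x = nn.as_tensor(x)
    block = init_parameters(SqueezeExcite(x.shape[1], R), seed)
    return block(x)


# ---------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------

class Encoder(Module):
    """Five downsampling units: 7x7 stride-2 conv (+BN+ReLU) with 3x3
    max pooling, then four bottleneck stages.  ``forward`` returns every
    stage output (including the pre-pool 7x7-conv map) for skip use."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        c_stem = config.scaled(_STEM_OUT)
        self.stem_conv = Conv2d(config.in_channels, c_stem, 7, stride=2,
                                padding=3, bias=False)
        self.stem_bn = BatchNorm2d(c_stem)
        self.pool = MaxPool2d(3, 2, 1)
        self.stages = ModuleList()
        in_ch = c_stem
        for i, n_blocks in enumerate(config.block_counts):
            mid = config.scaled(_STAGE_MID[i])
            out = config.scaled(_STAGE_OUT[i])
            blocks = ModuleList()
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                blocks.append(Bottleneck(in_ch if b == 0 else out, mid, out,
                                         stride=stride))
            self.stages.append(blocks)
            in_ch = out
        self.stage_channels = [c_stem] + [config.scaled(c) for c in _STAGE_OUT]

    def forward(self, x) -> dict:
        x = nn.as_tensor(x)
        if x.shape[2] % 32 != 0 or x.shape[3] % 32 != 0:
            raise ShapeError(f"input side must be divisible by 32, "
                             f"got {x.shape[2]}x{x.shape[3]}")
        feats = {}
        y = nn.relu(self.stem_bn(self.stem_conv(x)))
        feats["conv1"] = y            # pre-pool, C=64w at S/2
        y = self.pool(y)
        feats["unit1"] = y            # post-pool, S/4
        for i, blocks in enumerate(self.stages):
            for block in blocks:
                y = block(y)
            feats[f"unit{i + 2}"] = y
        return feats


def build_encoder(config: NetworkConfig, seed: int = 0) -> Encoder:
    return init_parameters(Encoder(config), seed)


# ---------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------

class DecoderUnit(Module):
    """One upsampling unit: bilinear 2x -> concat skip -> conv 1x1 ->
    conv 3x3 -> BN -> ReLU -> atrous conv 3x3 (dilation d) -> BN -> ReLU
    -> SE."""

    def __init__(self, in_channels: int, skip_channels: int,
                 out_channels: int, dilation: int = 2, reduction: int = 6):
        super().__init__()
        if min(in_channels, skip_channels, out_channels) < 1:
            raise ValueError("channel counts must be >= 1")
        self.up = UpsampleBilinear2x()
        self.conv1 = Conv2d(in_channels + skip_channels, out_channels, 1)
        self.conv3 = Conv2d(out_channels, out_channels, 3, padding=1,
                            bias=False)
        self.bn3 = BatchNorm2d(out_channels)
        self.atrous = Conv2d(out_channels, out_channels, 3, dilation=dilation,
                             padding=dilation, bias=False)
        self.bn_atrous = BatchNorm2d(out_channels)
        self.se = SqueezeExcite(out_channels, reduction)

    def forward(self, x, skip):
        x, skip = nn.as_tensor(x), nn.as_tensor(skip)
        y = self.up(x)
        if y.shape[2:] != skip.shape[2:]:
            raise ShapeError(f"skip spatial size {skip.shape[2:]} does not "
                             f"match upsampled size {y.shape[2:]}")
        y = nn.concat([y, skip], axis=1)
        y = self.conv1(y)
        y = nn.relu(self.bn3(self.conv3(y)))
        y = nn.relu(self.bn_atrous(self.atrous(y)))
        return self.se(y)


def build_decoder_unit(in_channels: int, skip_channels: int,
                       out_channels: int, d: int = 2, R: int = 6,
                       seed: int = 0) -> DecoderUnit:
    return init_parameters(
        DecoderUnit(in_channels, skip_channels, out_channels, d, R), seed)


# ---------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------

class SegmentationNet(Module):
    """Full encoder--decoder network: probability map in [0, 1] at input
    resolution.  Skip sources are the stage-4/3/2 residual outputs and the
    pre-pool 7x7-conv map."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        self.encoder = Encoder(config)
        dil = config.dilations()
        R = config.se_reduction_R
        sc = config.scaled
        # (input, skip, output) channel plan per decoder unit
        plan = [(sc(2048), sc(1024), sc(1024)),
                (sc(1024), sc(512), sc(512)),
                (sc(512), sc(256), sc(256)),
                (sc(256), sc(_STEM_OUT), sc(_STEM_OUT))]
        self.units = ModuleList(
            DecoderUnit(i, s, o, dilation=d, reduction=R)
            for (i, s, o), d in zip(plan, dil))
        self.head_up = UpsampleBilinear2x()
        self.head_conv = Conv2d(sc(_STEM_OUT), 1, 1)

    def forward(self, x):
        out, _, _ = self.forward_with_intermediates(x)
        return out

    def forward_with_intermediates(self, x):
        feats = self.encoder(x)
        skips = [feats["unit4"], feats["unit3"], feats["unit2"], feats["conv1"]]
        y = feats["unit5"]
        decoder_feats = []
        for unit, skip in zip(self.units, skips):
            y = unit(y, skip)
            decoder_feats.append(y)
        y = self.head_up(y)
        out = nn.sigmoid(self.head_conv(y))
        decoder_feats.append(out)
        return out, feats, decoder_feats


def assemble_network(config: NetworkConfig | None = None,
                     seed: int = 0) -> SegmentationNet:
    """Build and deterministically initialize the full network; loads
    pretrained encoder weights if the config names a source."""
    config = config or NetworkConfig()
    model = init_parameters(SegmentationNet(config), seed)
    if config.pretrained_source is not None:
        load_pretrained_encoder(model, config.pretrained_source)
    return model


# ---------------------------------------------------------------------
# encoder weight transfer
# ---------------------------------------------------------------------

def save_encoder_weights(model: SegmentationNet, path) -> None:
    """Serialize the encoder's parameters (npz, name -> array)."""
    arrays = {name: p.data for name, p in model.encoder.named_parameters()}
    np.savez(path, **arrays)


def load_pretrained_encoder(model: SegmentationNet, source) -> dict:
    """Copy weights from an encoder archive into ``model``'s encoder where
    names and shapes match; the decoder is untouched.

    Returns a report ``{"matched": [...], "missing": [...],
    "unexpected": [...]}`` over encoder parameter names.  Transfer requires
    the full-width encoder (width_multiplier == 1): at any other width the
    shapes cannot match and a :class:`ConfigurationError` is raised.
    """
    if model.config.width_multiplier != 1:
        raise ConfigurationError(
            "pretrained encoder weights require width_multiplier == 1 "
            f"(got {model.config.width_multiplier})")
    archive = np.load(source)
    own = dict(model.encoder.named_parameters())
    matched, unexpected = [], []
    for name in archive.files:
        if name in own and own[name].data.shape == archive[name].shape:
            own[name].data = archive[name].astype(np.float32).copy()
            matched.append(name)
        else:
            unexpected.append(name)
    missing = sorted(set(own) - set(matched))
    return {"matched": sorted(matched), "missing": missing,
            "unexpected": sorted(unexpected)}
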