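"""The improved U-Net: residual depthwise-separable blocks, single- and
dual-branch builders, and a plain-convolution baseline.

The feature-extraction block replaces U-Net's ordinary convolution: a
3x3 depthwise convolution, a 1x1 pointwise convolution, batch
normalization, an identity residual shortcut (only when the block
preserves its channel count — a projection shortcut would add
parameters, and the whole point of the shortcut is that it adds none),
and the h-swish activation after the addition:

    y = h_swish( BN(PW(DW(x))) + x )        with h_swish(x) = x*ReLU6(x+3)/6

Both networks have five encoder/decoder levels with two blocks per
level: the encoder max-pools 2x2 between levels; the decoder upsamples
2x, concatenates the skip tensor and applies two blocks; a final 1x1
convolution yields per-class logits at full resolution. The dual-branch
variant runs two structurally identical, independently weighted encoders
(PCA spectra and hand-crafted features); at every level the two pre-pool
feature maps are concatenated and reduced back to the level width by a
1x1 convolution, forming the skip tensors and the bottleneck of a single
shared decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn import (
    BatchNorm2d,
    Conv3x3,
    DepthwiseConv3x3,
    Module,
    ModuleList,
    PointwiseConv,
    Tensor,
)

__all__ = [
    "NetConfig",
    "ModuleSpec",
    "h_swish",
    "FeatureExtractionModule",
    "PlainConvBlock",
    "SingleBranchUNet",
    "DualBranchUNet",
    "PlainUNet",
    "build_single_branch",
    "build_dual_branch",
    "build_plain_unet",
    "count_parameters",
    "module_parameter_count",
]

logger = logging.getLogger(__name__)


def h_swish(x):
    """h-swish activation, ``x * ReLU6(x + 3) / 6`` (plain numpy)."""
    x = np.asarray(x, dtype=float)
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


@dataclass
class NetConfig:
    """Architecture description.

    ``channels`` gives the width of each encoder level; the defaults
    follow the classic U-Net doubling ladder.
    Spatial inputs must be divisible by ``2 ** (levels - 1)``.
    """

    n_classes: int
    levels: int = 5
    modules_per_level: int = 2
    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    in_channels: int = 6
    in_channels_art: int | None = None  # dual branch; defaults to in_channels
    residual: bool = True
    branch_mode: str = "single"  # single | dual
    upsample_mode: str = "bilinear"  # bilinear | nearest
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != self.levels:
            raise ValueError("need one channel width per level")
        if self.branch_mode not in ("single", "dual"):
            raise ValueError(f"unknown branch_mode {self.branch_mode!r}")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.in_channels_art is None:
            self.in_channels_art = self.in_channels

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "levels": self.levels,
            "modules_per_level": self.modules_per_level,
            "channels": list(self.channels),
            "in_channels": self.in_channels,
            "in_channels_art": self.in_channels_art,
            "residual": self.residual,
            "branch_mode": self.branch_mode,
            "upsample_mode": self.upsample_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass
class ModuleSpec:
    """Channel contract of one feature-extraction block."""

    in_channels: int
    out_channels: int
    residual: bool = True

    @property
    def uses_residual(self) -> bool:
        # identity shortcuts only: a width change would need a projection
        return self.residual and self.in_channels == self.out_channels

    @property
    def parameter_count(self) -> int:
        """Closed form: depthwise 9*C_in + pointwise C_in*C_out + BN 2*C_out,
        independent of the residual toggle."""
        return (9 * self.in_channels
                + self.in_channels * self.out_channels
                + 2 * self.out_channels)


def module_parameter_count(spec: ModuleSpec) -> int:
    return spec.parameter_count


_warned_shortcut = False


class FeatureExtractionModule(Module):
    """Depthwise 3x3 -> pointwise 1x1 -> BN -> (+input) -> h-swish."""

    def __init__(self, spec: ModuleSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.depthwise = DepthwiseConv3x3(spec.in_channels, rng)
        self.pointwise = PointwiseConv(spec.in_channels, spec.out_channels,
                                       rng, bias=False)
        self.bn = BatchNorm2d(spec.out_channels)
        if spec.residual and not spec.uses_residual:
            global _warned_shortcut
            if not _warned_shortcut:
                logger.info(
                    "identity shortcut omitted where in_channels != "
                    "out_channels (identity-only residual rule)"
                )
                _warned_shortcut = True

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn(self.pointwise(self.depthwise(x)))
        if self.spec.uses_residual:
            out = ag.add(out, x)
        return ag.h_swish(out)


class PlainConvBlock(Module):
    """Ordinary 3x3 convolution -> BN -> ReLU (baseline U-Net block)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv3x3(in_channels, out_channels, rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


def _level_blocks(in_ch: int, width: int, n_modules: int, residual: bool,
                  rng: np.random.Generator,
                  block: str = "separable") -> ModuleList:
    """First block changes the width, the rest preserve it (so they can
    carry the identity shortcut)."""
    mods: list[Module] = []
    for i in range(n_modules):
        cin = in_ch if i == 0 else width
        if block == "separable":
            mods.append(FeatureExtractionModule(
                ModuleSpec(cin, width, residual=residual), rng))
        else:
            mods.append(PlainConvBlock(cin, width, rng))
    return ModuleList(mods)


def _run(blocks: ModuleList, x: Tensor) -> Tensor:
    for b in blocks:
        x = b(x)
    return x


class _Decoder(Module):
    """Shared decoder: upsample, 1x1 reduce, concat skip, two blocks."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator,
                 block: str = "separable"):
        super().__init__()
        ch = cfg.channels
        self.upsample_mode = cfg.upsample_mode
        reduces, stages = [], []
        for lvl in range(cfg.levels - 2, -1, -1):  # deepest first
            reduces.append(PointwiseConv(ch[lvl + 1], ch[lvl], rng))
            stages.append(_level_blocks(
                2 * ch[lvl], ch[lvl], cfg.modules_per_level, cfg.residual,
                rng, block=block))
        self.reduces = ModuleList(reduces)
        self.stages = ModuleList(stages)
        self.head = PointwiseConv(ch[0], cfg.n_classes, rng, bias=True)

    def forward(self, bottom: Tensor, skips: list[Tensor]) -> Tensor:
        x = bottom
        for reduce, stage, skip in zip(self.reduces, self.stages,
                                       reversed(skips)):
            x = reduce(ag.upsample2(x, self.upsample_mode))
            x = _run(stage, ag.concat_channels([skip, x]))
        return self.head(x)


class _Encoder(Module):
    def __init__(self, cfg: NetConfig, in_channels: int,
                 rng: np.random.Generator, block: str = "separable"):
        super().__init__()
        ch = cfg.channels
        stages = []
        for lvl in range(cfg.levels):
            cin = in_channels if lvl == 0 else ch[lvl - 1]
            stages.append(_level_blocks(
                cin, ch[lvl], cfg.modules_per_level, cfg.residual, rng,
                block=block))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Pre-pool feature maps of every level (the last is the bottleneck)."""
        feats = []
        for lvl, stage in enumerate(self.stages):
            if lvl > 0:
                x = ag.max_pool2(x)
            x = _run(stage, x)
            feats.append(x)
        return feats


def _check_spatial(shape, divisor: int) -> None:
    h, w = shape[2], shape[3]
    if h % divisor or w % divisor:
        raise ValueError(
            f"input {h}x{w} is not divisible by {divisor} "
            f"(required by {int(np.log2(divisor))} poolings)"
        )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class SingleBranchUNet(Module):
    """Improved U-Net on one 6-channel input."""

    def __init__(self, cfg: NetConfig, block: str = "separable"):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = _Encoder(cfg, cfg.in_channels, rng, block=block)
        self.decoder = _Decoder(cfg, rng, block=block)

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        _check_spatial(x.shape, self.config.divisor)
        feats = self.encoder(x)
        return self.decoder(feats[-1], feats[:-1])


class PlainUNet(SingleBranchUNet):
    """Baseline with ordinary convolutions and ReLU, same topology."""

    def __init__(self, cfg: NetConfig):
        super().__init__(cfg, block="plain")


class DualBranchUNet(Module):
    """Two independent encoders (spectral and hand-crafted inputs) with
    per-level concat + 1x1 fusion feeding one shared decoder."""

    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder_pca = _Encoder(cfg, cfg.in_channels, rng)
        self.encoder_art = _Encoder(cfg, cfg.in_channels_art, rng)
        self.fusions = ModuleList([
            PointwiseConv(2 * c, c, rng) for c in cfg.channels
        ])
        self.decoder = _Decoder(cfg, rng)

    def forward(self, x_pca, x_art) -> Tensor:
        x_pca, x_art = _as_tensor(x_pca), _as_tensor(x_art)
        if x_pca.shape[2:] != x_art.shape[2:]:
            raise ValueError(
                f"branch inputs disagree in spatial size: "
                f"{x_pca.shape[2:]} vs {x_art.shape[2:]}"
            )
        _check_spatial(x_pca.shape, self.config.divisor)
        feats_p = self.encoder_pca(x_pca)
        feats_a = self.encoder_art(x_art)
        fused = [
            fuse(ag.concat_channels([fp, fa]))
            for fuse, fp, fa in zip(self.fusions, feats_p, feats_a)
        ]
        return self.decoder(fused[-1], fused[:-1])


def build_single_branch(cfg: NetConfig) -> SingleBranchUNet:
    if cfg.branch_mode != "single":
        raise ValueError("config.branch_mode must be 'single'")
    return SingleBranchUNet(cfg)


def build_dual_branch(cfg: NetConfig) -> DualBranchUNet:
    if cfg.branch_mode != "dual":
        raise ValueError("config.branch_mode must be 'dual'")
    return DualBranchUNet(cfg)


def build_plain_unet(cfg: NetConfig) -> PlainUNet:
    return PlainUNet(cfg)


def count_parameters(model: Module) -> int:
    """Total trainable scalar count."""
    return int(sum(p.data.size for p in model.parameters()))
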