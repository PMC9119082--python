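"""Encoder-decoder convolutional branch with iterative feature aggregation.

The encoder is a ResNet-style stack of basic (two-conv) residual blocks:
a stride-1 stem followed by four stages.  Three stages stride by 2 and the
deepest stage keeps stride 1, so the bottleneck sits at 1/8 of the input
resolution — the scale at which long-range features are fused in.  The
reference widths/depths are 64/128/256/512 at depths 3/4/6/3 (ResNet-34
like), which lands the full model on its ~30M-parameter budget.

Skip connections are replaced by *iterative aggregation*: an ordered list of
nodes, each of which upsamples the feature map one scale below, projects it
with a 1x1 convolution to the finer map's width and element-wise adds it.
Nodes run shallow-to-deep in rounds, so later nodes consume earlier nodes'
outputs; the default plan is the full triangle over the scales {1,2,4,8}.
An empty plan degrades exactly to plain skip connections.

The decoder mirrors the encoder with three bilinear x2 upsampling stages;
each stage adds the matching aggregated skip (after 1x1 width projection)
and applies two 3x3 conv+BN+ReLU layers, then a 1x1 head produces per-class
scores at full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Dropout,
    Module,
    ModuleList,
    Tensor,
    upsample2x,
)


@dataclass(frozen=True)
class EncoderConfig:
    stage_depths: tuple[int, ...] = (3, 4, 6, 3)
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    stage_strides: tuple[int, ...] = (2, 2, 2, 1)
    stem_width: int = 64
    in_channels: int = 1

    def __post_init__(self):
        if not (len(self.stage_depths) == len(self.stage_widths)
                == len(self.stage_strides) == 4):
            raise ValueError("encoder needs exactly 4 stages")
        if any(b > a for a, b in zip(self.stage_widths[1:], self.stage_widths)):
            raise ValueError("stage widths must be nondecreasing")

    @property
    def bottleneck_width(self) -> int:
        return self.stage_widths[-1]

    def skip_channels(self) -> dict[int, int]:
        """Channel count of the pyramid map at each spatial divisor."""
        return {1: self.stem_width, 2: self.stage_widths[0],
                4: self.stage_widths[1], 8: self.stage_widths[2]}


@dataclass
class FeaturePyramid:
    """Per-scale maps: divisor -> Tensor, plus the deepest (bottleneck) map."""

    levels: dict[int, Tensor]
    bottleneck: Tensor


@dataclass(frozen=True)
class AggregationPlan:
    """Ordered aggregation nodes (finer_divisor, coarser_divisor).

    Every node's coarser level must be exactly one scale (factor 2) below
    its finer level.  ``triangular()`` builds the reference full-triangle
    iteration; ``empty()`` reduces the network to plain skip connections.
    """

    nodes: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        for finer, coarser in self.nodes:
            if coarser != 2 * finer:
                raise ValueError(
                    f"node ({finer},{coarser}): coarser level must be exactly "
                    f"one scale below the finer level")

    @staticmethod
    def empty() -> "AggregationPlan":
        return AggregationPlan(())

    @staticmethod
    def triangular(scales=(1, 2, 4, 8)) -> "AggregationPlan":
        nodes = []
        n = len(scales) - 1
        for rnd in range(n):
            for i in range(n - rnd):
                nodes.append((scales[i], scales[i + 1]))
        return AggregationPlan(tuple(nodes))


def check_divisible(h: int, w: int, divisor: int = 8):
    if h % divisor or w % divisor:
        raise ValueError(
            f"input spatial dims ({h}x{w}) must be divisible by {divisor}; "
            f"pad the image to the next multiple of {divisor} first")


class BasicBlock(Module):
    """Two 3x3 conv+BN with identity (or 1x1-projected) residual."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, rng, stride=stride, padding=0)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return (y + shortcut).relu()


class Encoder(Module):
    def __init__(self, cfg: EncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.stem_conv = Conv2d(cfg.in_channels, cfg.stem_width, 3, rng)
        self.stem_bn = BatchNorm2d(cfg.stem_width)
        stages = []
        in_ch = cfg.stem_width
        for depth, width, stride in zip(cfg.stage_depths, cfg.stage_widths,
                                        cfg.stage_strides):
            blocks = [BasicBlock(in_ch, width, stride, rng)]
            blocks += [BasicBlock(width, width, 1, rng) for _ in range(depth - 1)]
            stages.append(ModuleList(blocks))
            in_ch = width
        self.stages = ModuleList(stages)

    def __call__(self, x: Tensor) -> FeaturePyramid:
        """Returns per-divisor maps {1,2,4,8} plus the bottleneck (also /8).

        The first (shallowest) map produced at each divisor feeds the skip
        set; the stride-1 deep stage refines the /8 map into the bottleneck.
        """
        cfg = self.cfg
        _, c, h, w = x.data.shape
        if c != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channel(s), got {c}")
        check_divisible(h, w)
        y = self.stem_bn(self.stem_conv(x)).relu()
        levels = {1: y}
        divisor = 1
        for stage, stride in zip(self.stages, cfg.stage_strides):
            for block in stage:
                y = block(y)
            divisor *= stride
            levels.setdefault(divisor, y)
        return FeaturePyramid(levels={k: levels[k] for k in (1, 2, 4, 8)},
                              bottleneck=y)


def encode(encoder: Encoder, x: Tensor) -> FeaturePyramid:
    """Functional alias for running the encoder."""
    return encoder(x)


class IterativeAggregator(Module):
    """Applies an :class:`AggregationPlan` with one 1x1 projection per node."""

    def __init__(self, plan: AggregationPlan, skip_channels: dict[int, int], rng):
        super().__init__()
        self.plan = plan
        self.skip_channels = dict(skip_channels)
        projs = []
        for finer, coarser in plan.nodes:
            if finer not in skip_channels or coarser not in skip_channels:
                raise ValueError(f"plan references unknown pyramid level "
                                 f"({finer},{coarser})")
            proj = Conv2d(skip_channels[coarser], skip_channels[finer], 1,
                          rng, padding=0)
            # zero-init: every aggregation node starts as an additive identity
            # (plain skip) and learns how much coarse context to mix in
            proj.weight.data[:] = 0
            projs.append(proj)
        self.projs = ModuleList(projs)

    def __call__(self, pyramid: FeaturePyramid) -> dict[int, Tensor]:
        state = dict(pyramid.levels)
        for (finer, coarser), proj in zip(self.plan.nodes, self.projs):
            up = upsample2x(state[coarser])
            contrib = proj(up)
            if contrib.data.shape != state[finer].data.shape:
                raise ValueError(
                    f"aggregation node ({finer},{coarser}): projected shape "
                    f"{contrib.data.shape} != finer shape {state[finer].data.shape}")
            state[finer] = state[finer] + contrib
        return {k: state[k] for k in (1, 2, 4)}


def iterative_aggregate(pyramid: FeaturePyramid,
                        aggregator: IterativeAggregator) -> dict[int, Tensor]:
    """Functional alias: aggregated skip maps at divisors {1, 2, 4}."""
    return aggregator(pyramid)


class Decoder(Module):
    """Cascaded x2 upsampling from the fused bottleneck to class scores."""

    def __init__(self, bottleneck_width: int, skip_channels: dict[int, int],
                 n_classes: int, rng, widths: tuple[int, ...] = (256, 128, 64),
                 dropout_rate: float = 0.0, dropout_rng=None):
        super().__init__()
        self.widths = widths
        in_ch = bottleneck_width
        stages = []
        for width, skip_div in zip(widths, (4, 2, 1)):
            stage = Module()
            stage.proj_in = Conv2d(in_ch, width, 1, rng, padding=0)
            stage.proj_skip = Conv2d(skip_channels[skip_div], width, 1, rng, padding=0)
            stage.conv1 = Conv2d(width, width, 3, rng)
            stage.bn1 = BatchNorm2d(width)
            stage.conv2 = Conv2d(width, width, 3, rng)
            stage.bn2 = BatchNorm2d(width)
            stage.drop = Dropout(dropout_rate, dropout_rng or np.random.default_rng(0))
            stages.append(stage)
            in_ch = width
        self.stages = ModuleList(stages)
        self.head = Conv2d(widths[-1], n_classes, 1, rng, padding=0)

    def __call__(self, fused: Tensor, skips: dict[int, Tensor]) -> Tensor:
        for div, stage in zip((4, 2, 1), self.stages):
            if div not in skips:
                raise ValueError(f"missing aggregated skip at divisor {div}")
            y = upsample2x(fused)
            y = stage.proj_in(y) + stage.proj_skip(skips[div])
            y = stage.bn1(stage.conv1(y)).relu()
            y = stage.bn2(stage.conv2(y)).relu()
            fused = stage.drop(y)
        return self.head(fused)


def decode(decoder: Decoder, fused: Tensor, skips: dict[int, Tensor]) -> Tensor:
    return decoder(fused, skips)
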