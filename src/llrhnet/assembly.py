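"""Composition of the two branches into the full segmentation network.

Four ablation variants are supported:

1. plain ResNet encoder-decoder (classic skip connections);
2. variant 1 plus iterative-aggregation skip connections;
3. variant 1 plus the transformer global branch (plain skips);
4. the full model: iterative aggregation and the global branch.

The two branches meet at the bottleneck (1/8 resolution, bottleneck width):
the transformer's spatial map is element-wise *added* to the convolutional
bottleneck, so a zeroed global branch degrades exactly to the local model.
The decoder turns the fused map into per-class scores; `forward` applies a
per-pixel softmax over {background, lesion class A, lesion class B}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .global_branch import GlobalBranch, TransformerConfig
from .local_branch import (
    AggregationPlan,
    Decoder,
    Encoder,
    EncoderConfig,
    IterativeAggregator,
    check_divisible,
)
from .nn import DTYPE, Module, Tensor, no_grad

VARIANT_DESCRIPTIONS = {
    1: "plain encoder-decoder backbone",
    2: "backbone + iterative aggregation",
    3: "backbone + global branch",
    4: "full model (iterative aggregation + global branch)",
}


@dataclass(frozen=True)
class NetConfig:
    """Complete architectural description of one network variant."""

    variant: int = 4
    n_classes: int = 3
    in_channels: int = 1
    encoder: EncoderConfig | None = None
    plan: AggregationPlan | None = None
    transformer: TransformerConfig | None = None
    decoder_widths: tuple[int, ...] = (256, 128, 64)
    dropout: float = 0.3

    def __post_init__(self):
        if self.variant not in VARIANT_DESCRIPTIONS:
            raise ValueError("variant must be in {1,2,3,4}")
        if self.variant in (1, 3) and self.plan is not None and self.plan.nodes:
            raise ValueError(f"variant {self.variant} uses plain skips; "
                             "the aggregation plan must be empty")
        if self.variant in (1, 2) and self.transformer is not None:
            raise ValueError(f"variant {self.variant} has no global branch; "
                             "transformer config must be None")

    def resolved(self) -> "NetConfig":
        """Fill in reference defaults for the unset components."""
        enc = self.encoder or EncoderConfig(in_channels=self.in_channels)
        plan = self.plan
        if plan is None:
            plan = (AggregationPlan.triangular() if self.variant in (2, 4)
                    else AggregationPlan.empty())
        tf = self.transformer
        if tf is None and self.variant in (3, 4):
            tf = TransformerConfig(in_channels=self.in_channels,
                                   dropout=self.dropout)
        return NetConfig(self.variant, self.n_classes, self.in_channels,
                         enc, plan, tf, self.decoder_widths, self.dropout)

    @property
    def uses_global_branch(self) -> bool:
        return self.variant in (3, 4)


@dataclass
class SegmentationOutput:
    """Per-pixel class probabilities (B,C,H,W) and the argmax label map."""

    class_probabilities: np.ndarray
    labels: np.ndarray


def fuse_bottleneck(local_map: Tensor, global_map: Tensor) -> Tensor:
    """Element-wise additive fusion of the two bottleneck maps."""
    if local_map.data.shape != global_map.data.shape:
        raise ValueError(f"bottleneck shape mismatch: {local_map.data.shape} "
                         f"vs {global_map.data.shape}")
    return local_map + global_map


class LLRHNet(Module):
    """The assembled two-branch network (see module docstring)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        super().__init__()
        cfg = cfg.resolved()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        enc = cfg.encoder
        self.encoder = Encoder(enc, rng)
        self.aggregator = IterativeAggregator(cfg.plan, enc.skip_channels(), rng)
        if cfg.uses_global_branch:
            self.global_branch = GlobalBranch(cfg.transformer, enc.bottleneck_width,
                                              rng, self.dropout_rng)
        else:
            self.global_branch = None
        self.decoder = Decoder(enc.bottleneck_width, enc.skip_channels(),
                               cfg.n_classes, rng, widths=cfg.decoder_widths,
                               dropout_rate=cfg.dropout,
                               dropout_rng=self.dropout_rng)

    @property
    def spatial_divisor(self) -> int:
        """Input dims must divide lcm(8, P)."""
        if self.cfg.uses_global_branch:
            return int(np.lcm(8, self.cfg.transformer.patch_size))
        return 8

    def logits(self, x: Tensor) -> Tensor:
        _, _, h, w = x.data.shape
        check_divisible(h, w, self.spatial_divisor)
        pyramid = self.encoder(x)
        skips = self.aggregator(pyramid)
        bottleneck = pyramid.bottleneck
        if self.global_branch is not None:
            bottleneck = fuse_bottleneck(bottleneck, self.global_branch(x))
        return self.decoder(bottleneck, skips)

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x)


def build(cfg: NetConfig, seed: int = 0) -> LLRHNet:
    """Construct a network variant; validates config consistency."""
    return LLRHNet(cfg, seed=seed)


def forward(net: LLRHNet, image: np.ndarray) -> SegmentationOutput:
    """Inference: image (C,H,W) or (B,C,H,W) -> softmax probabilities + labels."""
    arr = np.asarray(image, dtype=DTYPE)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    was_training = net.training
    net.eval()
    try:
        with no_grad():
            probs = net.logits(Tensor(arr)).softmax(axis=1).data
    finally:
        net.train(was_training)
    if squeeze:
        probs = probs[0]
        labels = probs.argmax(axis=0)
    else:
        labels = probs.argmax(axis=1)
    return SegmentationOutput(class_probabilities=probs,
                              labels=labels.astype(np.uint8))


def parameter_count(cfg: NetConfig, seed: int = 0) -> int:
    """Trainable-parameter count of a variant (input-size independent)."""
    return build(cfg, seed=seed).n_parameters()
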