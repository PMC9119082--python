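import numpy as np
import pytest

from llrhnet.assembly import NetConfig
from llrhnet.global_branch import TransformerConfig
from llrhnet.local_branch import EncoderConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_encoder(in_channels: int = 1) -> EncoderConfig:
    """A narrow encoder for fast structural tests (same topology as reference)."""
    return EncoderConfig(stage_depths=(1, 1, 1, 1), stage_widths=(8, 16, 24, 32),
                         stage_strides=(2, 2, 2, 1), stem_width=8,
                         in_channels=in_channels)


def tiny_transformer(patch_size: int = 8, in_channels: int = 1) -> TransformerConfig:
    return TransformerConfig(patch_size=patch_size, embed_width=32, n_layers=1,
                             n_heads=4, mlp_ratio=2, in_channels=in_channels)


def tiny_net(variant: int = 4, n_classes: int = 3) -> NetConfig:
    return NetConfig(
        variant=variant, n_classes=n_classes,
        encoder=tiny_encoder(),
        transformer=tiny_transformer() if variant in (3, 4) else None,
        decoder_widths=(24, 16, 8),
        dropout=0.0,
    )


@pytest.fixture
def random_mask_pairs():
    """Seeded random boolean mask pairs on small lattices (oracle fodder)."""
    gen = np.random.default_rng(777)
    pairs = []
    for _ in range(40):
        h, w = gen.integers(2, 33, size=2)
        density = gen.uniform(0.05, 0.6)
        p = gen.random((h, w)) < density
        g = gen.random((h, w)) < density
        pairs.append((p, g))
    return pairs
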