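"""Transformer branch: patch tokenization, multi-head self-attention, and
re-mapping of the token sequence to a spatial feature map.

An image of size H x W is cut into non-overlapping P x P patches by a
stride-P convolution, giving N = HW/P^2 tokens of width d in row-major
patch order; fixed sinusoidal positional encodings over the token index are
added.  Each transformer layer is the standard pre-norm residual block

    x~ = MSA(LN(x)) + x
    x  = MLP(LN(x~)) + x~

with h-head scaled dot-product attention (per-head scale 1/sqrt(d/h), head
outputs concatenated then linearly projected back to width d) and a two-
layer GELU MLP of hidden width ``mlp_ratio * d``.  The output sequence is
reshaped row-major to (H/P) x (W/P), projected by a 1x1 convolution to the
local branch's bottleneck width, and bilinearly resized to H/8 x W/8 (an
identity resize when P = 8) for fusion at the bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    DTYPE,
    Conv2d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Tensor,
    interpolate_bilinear,
)
from .nn.tensor import concat

PATCH_SIZES = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class TransformerConfig:
    patch_size: int = 8
    embed_width: int = 512
    n_layers: int = 2
    n_heads: int = 8
    mlp_ratio: int = 4
    dropout: float = 0.0
    in_channels: int = 1

    def __post_init__(self):
        if self.embed_width % self.n_heads:
            raise ValueError("embed width must be divisible by the head count")
        if self.patch_size not in PATCH_SIZES:
            raise ValueError(f"patch size must be one of {PATCH_SIZES}")

    @property
    def head_width(self) -> int:
        return self.embed_width // self.n_heads


def sinusoidal_encoding(n_tokens: int, width: int) -> np.ndarray:
    """Fixed sine/cosine positional table over the row-major token index."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(width // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / width)
    pe = np.zeros((n_tokens, width))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe.astype(DTYPE)


def token_count(h: int, w: int, patch: int) -> int:
    """N = HW / P^2 for a P-divisible image."""
    if h % patch or w % patch:
        raise ValueError(f"image dims ({h}x{w}) not divisible by patch size {patch}")
    return (h // patch) * (w // patch)


# ---------------------------------------------------------------------------
# Functional attention primitives
# ---------------------------------------------------------------------------

def attention_single(seq: Tensor, wq: Tensor, wk: Tensor, wv: Tensor):
    """Scaled dot-product self-attention y = softmax(QK^T/sqrt(d_q)) V.

    ``seq`` has shape (..., N, d); the projections are (d, d_q/k/v) with
    d_q = d_k.  Returns (output, row-stochastic attention weights).
    """
    if wq.data.shape[1] != wk.data.shape[1]:
        raise ValueError("query and key projection widths must match")
    if wq.data.shape[0] != seq.data.shape[-1]:
        raise ValueError("projection input width does not match token width")
    q = seq @ wq
    k = seq @ wk
    v = seq @ wv
    dq = q.data.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
        * (1.0 / np.sqrt(dq))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


def attention_multi(seq: Tensor, wqs, wks, wvs, w_out: Tensor):
    """Multi-head attention: per-head single attention, concat, project."""
    outs = [attention_single(seq, wq, wk, wv)[0] for wq, wk, wv in zip(wqs, wks, wvs)]
    return concat(outs, axis=-1) @ w_out


class MultiHeadSelfAttention(Module):
    """Fused-projection MSA used inside the network (heads via reshape)."""

    def __init__(self, cfg: TransformerConfig, rng):
        super().__init__()
        d = cfg.embed_width
        self.cfg = cfg
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.w_out = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.data.shape
        h, dh = self.cfg.n_heads, self.cfg.head_width
        def split(t: Tensor) -> Tensor:  # (B,N,d) -> (B,h,N,dh)
            return t.reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        y = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.w_out(y)


class TransformerLayer(Module):
    """Pre-norm residual block: LN -> MSA -> add; LN -> MLP(GELU) -> add."""

    def __init__(self, cfg: TransformerConfig, rng, dropout_rng=None):
        super().__init__()
        d = cfg.embed_width
        self.ln1 = LayerNorm(d)
        self.msa = MultiHeadSelfAttention(cfg, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, cfg.mlp_ratio * d, rng)
        self.fc2 = Linear(cfg.mlp_ratio * d, d, rng)
        self.drop = Dropout(cfg.dropout, dropout_rng or np.random.default_rng(0))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.msa(self.ln1(x)) + x
        y = self.fc2(self.drop(self.fc1(self.ln2(x)).gelu()))
        return y + x


def transformer_layer(layer: TransformerLayer, x: Tensor) -> Tensor:
    return layer(x)


class GlobalBranch(Module):
    """Patch embedding + transformer stack + token-to-map head."""

    def __init__(self, cfg: TransformerConfig, bottleneck_width: int, rng,
                 dropout_rng=None):
        super().__init__()
        self.cfg = cfg
        self.embed = Conv2d(cfg.in_channels, cfg.embed_width, cfg.patch_size,
                            rng, stride=cfg.patch_size, padding=0)
        self.layers = ModuleList(
            [TransformerLayer(cfg, rng, dropout_rng) for _ in range(cfg.n_layers)])
        self.to_bottleneck = Conv2d(cfg.embed_width, bottleneck_width, 1, rng,
                                    padding=0)
        # zero-init the fusion projection: the branch starts as an additive
        # identity at the bottleneck and learns its contribution, instead of
        # perturbing the convolutional features with a random map at step 0
        self.to_bottleneck.weight.data[:] = 0

    def patchify_embed(self, x: Tensor) -> Tensor:
        """(B,C,H,W) -> (B, N, d) row-major token sequence with positions."""
        _, _, h, w = x.data.shape
        n = token_count(h, w, self.cfg.patch_size)
        t = self.embed(x)                      # (B, d, H/P, W/P)
        b, d, gh, gw = t.data.shape
        seq = t.reshape(b, d, gh * gw).transpose(0, 2, 1)   # row-major
        pe = sinusoidal_encoding(n, d).astype(t.data.dtype)
        return seq + Tensor(pe)

    def tokens_to_map(self, seq: Tensor, image_hw: tuple[int, int]) -> Tensor:
        """Row-major reshape to (H/P, W/P), 1x1 projection, resize to H/8."""
        h, w = image_hw
        p = self.cfg.patch_size
        gh, gw = h // p, w // p
        b, n, d = seq.data.shape
        if n != gh * gw:
            raise ValueError(f"token count {n} != (H/P)(W/P) = {gh * gw}")
        fmap = seq.transpose(0, 2, 1).reshape(b, d, gh, gw)
        fmap = self.to_bottleneck(fmap)
        return interpolate_bilinear(fmap, (h // 8, w // 8))

    def __call__(self, x: Tensor) -> Tensor:
        _, _, h, w = x.data.shape
        seq = self.patchify_embed(x)
        for layer in self.layers:
            seq = layer(seq)
        return self.tokens_to_map(seq, (h, w))


def tokens_to_map_reshape(seq: np.ndarray, grid_hw: tuple[int, int]) -> np.ndarray:
    """Pure row-major (N,d) -> (d, H/P, W/P) reshape (content unchanged)."""
    gh, gw = grid_hw
    n, d = seq.shape
    if n != gh * gw:
        raise ValueError("token count does not match the target grid")
    return np.ascontiguousarray(seq.reshape(gh, gw, d).transpose(2, 0, 1))


def map_to_tokens_reshape(fmap: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tokens_to_map_reshape`."""
    d, gh, gw = fmap.shape
    return np.ascontiguousarray(fmap.transpose(1, 2, 0).reshape(gh * gw, d))
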